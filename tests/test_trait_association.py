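"""Gene-trait correlations, the skewness statistic and its permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advenfib import (
    BulkSimConfig,
    BulkTraitDataset,
    CorrelationProfile,
    correlation_skewness,
    exhaustive_null,
    gene_trait_correlations,
    loading_for_target_r,
    permutation_test,
    run_trait_panel,
    simulate_bulk_trait_dataset,
)


def profile_from_r(r_values, trait="t") -> CorrelationProfile:
    """Build a profile directly from known correlation values."""
    r = pd.DataFrame({trait: np.asarray(r_values, dtype=float)},
                     index=[f"g{i}" for i in range(len(r_values))])
    return CorrelationProfile(r=r, valid=r.notna(), method="pearson")


def _dataset(expr, traits):
    idx = [f"s{i}" for i in range(len(expr))]
    return BulkTraitDataset(
        expression=pd.DataFrame(expr, index=idx,
                                columns=[f"g{j}" for j in range(np.shape(expr)[1])]),
        traits=pd.DataFrame(traits, index=idx, columns=["t0"]),
    )


class TestCorrelations:
    def test_gene_copied_from_trait_has_r_one(self):
        t = np.array([1.0, 3.0, 2.0, 5.0])
        data = _dataset(np.c_[t, -t], t)
        prof = gene_trait_correlations(data)
        assert prof.r.loc["g0", "t0"] == pytest.approx(1.0)
        assert prof.r.loc["g1", "t0"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_invalid(self):
        data = _dataset(np.c_[[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], [4.0, 5.0, 9.0])
        prof = gene_trait_correlations(data)
        assert not prof.valid.loc["g0", "t0"]
        assert prof.valid.loc["g1", "t0"]
        assert prof.n_invalid == 1

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_naive_loop(self, method):
        rng = np.random.default_rng(0)
        expr = rng.random((10, 5))
        traits = rng.random((10, 3))
        idx = [f"s{i}" for i in range(10)]
        data = BulkTraitDataset(
            expression=pd.DataFrame(expr, index=idx,
                                    columns=[f"g{j}" for j in range(5)]),
            traits=pd.DataFrame(traits, index=idx,
                                columns=[f"t{j}" for j in range(3)]),
        )
        prof = gene_trait_correlations(data, method=method)
        from scipy import stats

        for j in range(5):
            for t in range(3):
                if method == "pearson":
                    expect = stats.pearsonr(expr[:, j], traits[:, t]).statistic
                else:
                    expect = stats.spearmanr(expr[:, j], traits[:, t]).statistic
                assert prof.r.iloc[j, t] == pytest.approx(expect, abs=1e-12)

    def test_missing_values_use_complete_pairs(self):
        expr = np.array([[1.0, 1.0], [2.0, np.nan], [3.0, 3.0], [4.0, 0.0]])
        traits = np.array([1.0, 2.0, 3.0, 4.0])
        data = _dataset(expr, traits)
        prof = gene_trait_correlations(data)
        assert prof.r.loc["g0", "t0"] == pytest.approx(1.0)
        from scipy import stats

        mask = ~np.isnan(expr[:, 1])
        expect = stats.pearsonr(expr[mask, 1], traits[mask]).statistic
        assert prof.r.loc["g1", "t0"] == pytest.approx(expect, abs=1e-12)


class TestSkewness:
    def test_mixed_signs_example(self):
        assert correlation_skewness([0.5, 0.3, -0.2]) == pytest.approx(0.6)

    def test_all_zero(self):
        assert correlation_skewness([0.0, 0.0]) == 0.0

    def test_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert correlation_skewness([]) == 0.0

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_identity_with_plain_sum(self, values):
        assert correlation_skewness(values) == pytest.approx(
            float(np.sum(values)), abs=1e-12
        )


class TestPermutationTest:
    def test_full_universe_is_degenerate(self):
        prof = profile_from_r([0.1, -0.2, 0.3])
        with pytest.warns(UserWarning, match="degenerate"):
            res = permutation_test(["g0", "g1", "g2"], prof, "t", B=100, seed=0)
        assert res.degenerate and res.p_upper == 0.0 and res.p_lower == 0.0

    def test_empty_intersection_errors(self):
        prof = profile_from_r([0.1, 0.2])
        with pytest.raises(ValueError, match="no members"):
            permutation_test(["nope"], prof, "t", B=10, seed=0)

    def test_matches_exhaustive_on_small_instance(self):
        rng = np.random.default_rng(1)
        prof = profile_from_r(rng.uniform(-0.5, 0.5, 10))
        gene_set = ["g0", "g3", "g7"]
        exact = exhaustive_null(gene_set, prof, "t")
        mc = permutation_test(gene_set, prof, "t", B=20_000, seed=2)
        for tail in ("p_upper", "p_lower"):
            p = getattr(exact, tail)
            se = np.sqrt(max(p * (1 - p), 1e-12) / 20_000)
            assert abs(getattr(mc, tail) - p) <= 3 * se + 1e-9

    def test_sign_antisymmetry_exact(self):
        """Negating every correlation negates S and swaps the exact tails."""
        rng = np.random.default_rng(3)
        r = rng.uniform(-0.6, 0.6, 9)
        gene_set = ["g1", "g4", "g6"]
        a = exhaustive_null(gene_set, profile_from_r(r), "t")
        b = exhaustive_null(gene_set, profile_from_r(-r), "t")
        assert b.S == pytest.approx(-a.S, abs=1e-12)
        assert b.p_upper == pytest.approx(a.p_lower, abs=1e-12)
        assert b.p_lower == pytest.approx(a.p_upper, abs=1e-12)

    def test_null_pvalues_uniform(self):
        """Under exchangeable genes the upper tail p is uniform (KS check)."""
        rng = np.random.default_rng(4)
        pvals = []
        for rep in range(500):
            prof = profile_from_r(rng.normal(0, 0.15, 50))
            genes = [f"g{i}" for i in rng.choice(50, size=5, replace=False)]
            res = permutation_test(genes, prof, "t", B=200, seed=int(rep))
            pvals.append(res.p_upper)
        grid = np.sort(pvals)
        ecdf = np.arange(1, 501) / 500
        ks = np.max(np.abs(ecdf - grid))
        assert ks < 1.358 / np.sqrt(500) + 1 / 200  # 95% band + grid slack


class TestExhaustiveNull:
    def test_single_member_universe_of_three(self):
        prof = profile_from_r([0.1, 0.2, 0.3])
        res = exhaustive_null(["g1"], prof, "t")  # r = 0.2
        assert res.p_upper == pytest.approx(1 / 3)
        assert res.p_lower == pytest.approx(1 / 3)

    def test_full_set_degenerate(self):
        prof = profile_from_r([0.1, 0.2])
        with pytest.warns(UserWarning):
            res = exhaustive_null(["g0", "g1"], prof, "t")
        assert res.p_upper == 0.0

    def test_cap_enforced(self):
        prof = profile_from_r(np.zeros(40))
        with pytest.raises(ValueError, match="max_subsets"):
            exhaustive_null([f"g{i}" for i in range(15)], prof, "t",
                            max_subsets=1000)


class TestTraitPanel:
    def test_single_cell_consistent_with_permutation_test(self):
        data, sets = simulate_bulk_trait_dataset(
            BulkSimConfig(n_segments=30, n_genes=80, n_traits=1,
                          planted_set_sizes=(12,), seed=5,
                          planted_effect=np.array([[0.6]]))
        )
        panel = run_trait_panel({"set_1": sets["set_1"]}, data, B=2000, seed=6)
        assert len(panel) == 1
        from advenfib import gene_trait_correlations as gtc

        prof = gtc(data)
        child = np.random.SeedSequence(entropy=6, spawn_key=(0, 0))
        solo = permutation_test(sets["set_1"], prof, "trait_1", B=2000, seed=child)
        row = panel.iloc[0]
        assert row["S"] == pytest.approx(solo.S)
        assert row["p_upper"] == solo.p_upper and row["p_lower"] == solo.p_lower

    def test_negative_planted_set_hits_lower_tail(self):
        lam = loading_for_target_r(0.5, 1.0)
        data, sets = simulate_bulk_trait_dataset(
            BulkSimConfig(n_segments=43, n_genes=300, n_traits=1,
                          planted_set_sizes=(23,), seed=8,
                          planted_effect=np.array([[-lam]]))
        )
        panel = run_trait_panel(sets, data, B=4000, seed=9)
        row = panel.iloc[0]
        assert row["p_lower"] < 0.05 and row["p_upper"] > 0.5
        assert row["significant"]

    def test_failed_cells_are_flagged_rows(self):
        data, sets = simulate_bulk_trait_dataset(
            BulkSimConfig(n_segments=20, n_genes=60, n_traits=1,
                          planted_set_sizes=(8,), seed=10)
        )
        panel = run_trait_panel(
            {"good": sets["set_1"], "bad": ["nonexistent"]}, data, B=500, seed=11
        )
        bad = panel[panel["set"] == "bad"].iloc[0]
        assert bad["error"] != "" and not bad["significant"]
        assert (panel[panel["set"] == "good"]["error"] == "").all()
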