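"""QC metrics, filter semantics, normalization, selection and purity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advenfib import (
    QCThresholds,
    SimConfig,
    apply_qc_filters,
    compute_qc_metrics,
    normalize_log,
    purity_check,
    select_mesenchymal,
    simulate_sc_dataset,
)
from conftest import make_adata


class TestQCMetrics:
    def test_simple_mito_fraction(self):
        adata = make_adata([[15, 85]], genes=["mt-1", "g1"], mito=["mt-1"])
        m = compute_qc_metrics(adata)
        assert m.loc["c0", "mito_fraction"] == pytest.approx(0.15)
        assert m.loc["c0", "umi_total"] == 100
        assert m.loc["c0", "genes_detected"] == 2

    def test_zero_cell_flagged_degenerate(self):
        adata = make_adata([[0, 0], [1, 2]], mito=["g0"])
        m = compute_qc_metrics(adata)
        assert m.loc["c0", "umi_total"] == 0
        assert m.loc["c0", "mito_fraction"] == 0.0
        assert bool(m.loc["c0", "is_degenerate"])

    @pytest.mark.parametrize("sparse_x", [False, True])
    def test_matches_bruteforce_loop(self, sparse_x):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(50, 20))
        mito = ["g0", "g1", "g2"]
        adata = make_adata(X, mito=mito, sparse_x=sparse_x)
        m = compute_qc_metrics(adata)
        for i in range(50):
            row = X[i]
            assert m.iloc[i]["genes_detected"] == (row > 0).sum()
            assert m.iloc[i]["umi_total"] == row.sum()
            expect = row[:3].sum() / row.sum() if row.sum() else 0.0
            assert m.iloc[i]["mito_fraction"] == pytest.approx(expect)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_qc_metrics(make_adata(np.empty((0, 3))))

    def test_mito_prefix_fallback(self):
        adata = make_adata([[5, 5]], genes=["mt-Nd1", "Actb"])
        adata.var = adata.var.drop(columns="is_mito")
        m = compute_qc_metrics(adata)
        assert m.loc["c0", "mito_fraction"] == pytest.approx(0.5)


class TestQCFilters:
    def test_boundary_cells_kept_strict_inequalities(self, qc_boundary_fixture):
        adata, expected = qc_boundary_fixture
        res = apply_qc_filters(compute_qc_metrics(adata))
        assert res.table["decision"].to_dict() == expected
        assert res.table.loc["doublet", "reasons"] == "high_umi"
        assert "low_genes" in res.table.loc["low_genes", "reasons"]

    def test_partition_is_complete(self, qc_boundary_fixture):
        adata, _ = qc_boundary_fixture
        res = apply_qc_filters(compute_qc_metrics(adata))
        combined = res.kept.append(res.removed_low_quality).append(res.removed_doublet)
        assert sorted(combined) == sorted(adata.obs_names)

    def test_generator_doublets_all_removed(self):
        """Planted doublets (~20k UMIs) always trip the >15 000 rule."""
        adata, truth = simulate_sc_dataset(SimConfig(n_cells=1000, seed=5))
        res = apply_qc_filters(compute_qc_metrics(adata))
        planted = set(truth.cells.index[truth.cells["is_doublet"]])
        assert planted <= set(res.removed_doublet)

    @given(
        min_genes=st.integers(0, 30),
        max_mito=st.floats(0.05, 1.0),
        max_umi=st.integers(1, 200),
        delta_genes=st.integers(0, 10),
        delta_umi=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_relaxing_thresholds_never_shrinks_kept(
        self, min_genes, max_mito, max_umi, delta_genes, delta_umi
    ):
        rng = np.random.default_rng(7)
        metrics = pd.DataFrame(
            {
                "genes_detected": rng.integers(0, 40, 80),
                "umi_total": rng.integers(0, 250, 80),
                "mito_fraction": rng.random(80),
            },
            index=[f"c{i}" for i in range(80)],
        )
        strict = apply_qc_filters(
            metrics, QCThresholds(min_genes, max_mito, max_umi)
        )
        relaxed = apply_qc_filters(
            metrics,
            QCThresholds(
                max(min_genes - delta_genes, 0),
                min(max_mito + 0.2, 1.0),
                max_umi + delta_umi,
            ),
        )
        assert set(strict.kept) <= set(relaxed.kept)

    def test_idempotent_on_kept_subset(self):
        rng = np.random.default_rng(1)
        metrics = pd.DataFrame(
            {
                "genes_detected": rng.integers(0, 3000, 100),
                "umi_total": rng.integers(0, 30_000, 100),
                "mito_fraction": rng.random(100) * 0.4,
            },
            index=[f"c{i}" for i in range(100)],
        )
        first = apply_qc_filters(metrics)
        second = apply_qc_filters(metrics.loc[first.kept])
        assert list(second.kept) == list(first.kept)
        assert len(second.removed_low_quality) == len(second.removed_doublet) == 0


class TestNormalize:
    def test_single_cell_example(self):
        adata = make_adata([[10, 0]])
        out = normalize_log(adata, scale=10)
        assert np.allclose(out.X, [[np.log(11), 0.0]])

    def test_zero_cell_stays_zero(self):
        out = normalize_log(make_adata([[0, 0], [1, 1]]))
        assert np.allclose(np.asarray(out.X)[0], 0.0)

    @pytest.mark.parametrize("sparse_x", [False, True])
    def test_matches_naive_loop(self, sparse_x):
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, size=(30, 15))
        out = normalize_log(make_adata(X, sparse_x=sparse_x), scale=500)
        got = out.X.toarray() if sparse_x else np.asarray(out.X)
        for i in range(30):
            tot = X[i].sum()
            expect = np.log1p(X[i] / tot * 500) if tot else np.zeros(15)
            assert np.allclose(got[i], expect)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            normalize_log(make_adata([[1]]), scale=0)


class TestSelectionAndPurity:
    def test_gate_gene_missing_is_error(self):
        with pytest.raises(KeyError, match="Pdgfrb"):
            select_mesenchymal(normalize_log(make_adata([[1, 2]])), "Pdgfrb")

    def test_nonzero_cells_retained(self):
        adata = normalize_log(
            make_adata([[1, 3], [0, 5]], genes=["Pdgfrb", "other"])
        )
        sel = select_mesenchymal(adata, "Pdgfrb", min_expr=0.0)
        assert list(sel.obs_names) == ["c0"]

    def test_all_zero_gate_warns_and_empties(self):
        adata = normalize_log(make_adata([[0, 2]], genes=["Pdgfrb", "other"]))
        with pytest.warns(UserWarning, match="gate"):
            sel = select_mesenchymal(adata, "Pdgfrb")
        assert sel.n_obs == 0

    def test_retention_matches_planted_prevalence(self):
        """Gate-positive retention tracks the fraction of cells with a
        nonzero gate-gene count in the generated data."""
        adata, _ = simulate_sc_dataset(
            SimConfig(n_cells=800, n_genes=300, seed=6, branch_program_size=5,
                      origin_program_size=5, marker_panel_size=5)
        )
        norm = normalize_log(adata)
        sel = select_mesenchymal(norm, "Pdgfrb")
        j = adata.var_names.get_loc("Pdgfrb")
        prevalence = (adata.X[:, j].toarray().ravel() > 0).mean()
        assert sel.n_obs / adata.n_obs == pytest.approx(prevalence)
        # NB closed form: P(count>0) = 1 - (theta/(theta+mu))^theta
        theta, mu = 2.0, 5.0
        expect = 1 - (theta / (theta + mu)) ** theta
        assert abs(prevalence - expect) < 0.05

    def test_absent_marker_untestable(self):
        rep = purity_check(normalize_log(make_adata([[1]])), ["Cd68"])
        assert rep.loc["Cd68", "status"] == "untestable"

    def test_all_zero_marker_passes(self):
        adata = normalize_log(make_adata([[0, 4], [0, 2]], genes=["Cd68", "g"]))
        rep = purity_check(adata, ["Cd68"])
        assert rep.loc["Cd68", "status"] == "pass"
        assert rep.loc["Cd68", "positive_fraction"] == 0.0

    def test_planted_contamination_fails(self):
        adata, _ = simulate_sc_dataset(
            SimConfig(n_cells=1000, n_genes=300, seed=8, contamination_rate=0.02,
                      branch_program_size=5, origin_program_size=5,
                      marker_panel_size=5)
        )
        rep = purity_check(normalize_log(adata), max_positive_fraction=0.01)
        assert (rep["status"] == "fail").all()
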