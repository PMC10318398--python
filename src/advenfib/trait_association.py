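"""Gene-set correlation skewness against plaque traits.

Relates trajectory gene sets to histology-quantified traits of
atherosclerotic plaque segments.  For each gene the Pearson (or Spearman)
correlation with a trait is computed across segments; a gene set's
*correlation skewness* is

    S = sum of positive correlations - sum of |negative correlations|

which algebraically equals the plain sum of the correlations (the identity
is kept explicit in :func:`correlation_skewness` and asserted by tests).
Significance comes from a permutation test: B random gene sets of the same
size are drawn from the genes with valid correlations for that trait, and
the upper empirical p-value is the frequency of random sets with strictly
higher skewness than the observed set.  The lower tail is reported
symmetrically so negatively skewed sets (gene sets anticorrelated with
detrimental traits) are testable.  No multiplicity correction is applied
across the set x trait grid by default (flagging uses raw p < alpha), with
an optional Benjamini-Hochberg switch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_PERM_CHUNK = 20_000  # permutation draws per vectorised block
_TIE_RTOL = 1e-9  # |S_b - S_obs| below this (relative) counts as a tie


def _tie_tol(s_obs: float) -> float:
    return _TIE_RTOL * max(1.0, abs(s_obs))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BulkTraitDataset:
    """Aligned segments x genes expression and segments x traits tables."""

    expression: pd.DataFrame
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.expression) < 3:
            raise ValueError("need at least 3 segments for correlations")
        if not self.expression.index.equals(self.traits.index):
            raise ValueError("expression and traits must share segment ids and order")


@dataclass
class CorrelationProfile:
    """Per (gene, trait) correlations with validity flags.

    ``r`` is genes x traits; ``valid`` is False where either vector is
    constant (or has fewer than 3 complete pairs), and those entries are
    excluded from all downstream sums.
    """

    r: pd.DataFrame
    valid: pd.DataFrame
    method: str

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).to_numpy().sum())

    def valid_r(self, trait: str) -> pd.Series:
        """Correlations of all valid genes for one trait."""
        mask = self.valid[trait]
        return self.r.loc[mask, trait]


@dataclass
class SkewnessTestResult:
    gene_set: str
    trait: str
    S: float
    n_genes_used: int
    B: int
    p_upper: float
    p_lower: float
    seed: int | None = None
    degenerate: bool = False

    @property
    def resolution(self) -> float:
        """Smallest nonzero empirical p reportable at this B."""
        return 1.0 / self.B if self.B else float("nan")


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def gene_trait_correlations(
    data: BulkTraitDataset, method: str = "pearson"
) -> CorrelationProfile:
    """Correlate every gene with every trait across segments.

    Pairs with a constant gene or trait vector (or <3 complete pairs after
    dropping missing values) are flagged invalid rather than returned as
    NaN surprises.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    expr = data.expression
    traits = data.traits
    genes, trait_names = expr.columns, traits.columns

    r = pd.DataFrame(np.nan, index=genes, columns=trait_names)
    valid = pd.DataFrame(False, index=genes, columns=trait_names)

    X = expr.to_numpy(dtype=float)
    if method == "spearman" and not np.isnan(X).any():
        X = stats.rankdata(X, axis=0)

    for trait in trait_names:
        t = traits[trait].to_numpy(dtype=float)
        t_missing = np.isnan(t)
        if (~t_missing).sum() < 3:
            warnings.warn(f"trait {trait!r}: fewer than 3 complete pairs; all invalid")
            continue
        if np.isnan(X).any() or t_missing.any():
            # pairwise-complete slow path
            for j, g in enumerate(genes):
                x = X[:, j]
                ok = ~(np.isnan(x) | t_missing)
                if ok.sum() < 3:
                    continue
                xs, ts = x[ok], t[ok]
                if method == "spearman":
                    xs, ts = stats.rankdata(xs), stats.rankdata(ts)
                if xs.std() == 0 or ts.std() == 0:
                    continue
                r.loc[g, trait] = float(np.corrcoef(xs, ts)[0, 1])
                valid.loc[g, trait] = True
            continue
        tv = stats.rankdata(t) if method == "spearman" else t
        t_sd = tv.std()
        x_sd = X.std(axis=0)
        ok = (x_sd > 0) & (t_sd > 0)
        if t_sd > 0:
            tc = (tv - tv.mean()) / t_sd
            xc = X - X.mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                rv = (xc * tc[:, None]).mean(axis=0) / x_sd
            r.loc[ok, trait] = rv[ok]
        valid[trait] = ok
    return CorrelationProfile(r=r, valid=valid, method=method)


# ---------------------------------------------------------------------------
# skewness statistic
# ---------------------------------------------------------------------------

def correlation_skewness(r_values) -> float:
    """Sum of positive correlations minus sum of |negative correlations|.

    The definition collapses algebraically to the plain sum of the
    correlations; it is computed literally here, and the identity is a
    tested invariant.  Empty input gives 0 with a warning.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        warnings.warn("correlation_skewness of empty input; returning 0")
        return 0.0
    if np.isnan(r).any():
        raise ValueError("r_values must come from valid pairs only (no NaN)")
    return float(r[r > 0].sum() - np.abs(r[r < 0]).sum())


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _resolve_universe(
    gene_set, profile: CorrelationProfile, trait: str, universe
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Common setup: valid-gene universe, its r values, observed S and m."""
    valid_r = profile.valid_r(trait)
    if universe is not None:
        valid_r = valid_r.loc[valid_r.index.intersection(pd.Index(universe))]
    uni_genes = valid_r.index
    members = uni_genes.intersection(pd.Index(list(gene_set)))
    m = len(members)
    if m == 0:
        raise ValueError(
            f"gene set has no members with valid correlations for trait {trait!r}"
        )
    s_obs = correlation_skewness(valid_r.loc[members].to_numpy())
    return uni_genes.to_numpy(), valid_r.to_numpy(), s_obs, m


def permutation_test(
    gene_set,
    profile: CorrelationProfile,
    trait: str,
    universe=None,
    B: int = 100_000,
    seed: int | np.random.SeedSequence = 0,
    gene_set_name: str = "gene_set",
) -> SkewnessTestResult:
    """Monte-Carlo permutation test of correlation skewness.

    Draws ``B`` random gene sets of the same size m (without replacement
    within each draw) from the genes with valid correlations for ``trait``
    (intersected with ``universe`` when given), and reports

    * ``p_upper``: frequency of random sets with S strictly greater than
      the observed S (the "higher correlation skewness" rule), and
    * ``p_lower``: frequency strictly smaller,

    with no +1 smoothing; the 1/B resolution is carried on the result.
    Draws whose S matches the observed value to within floating-point
    tolerance (e.g. a redraw of the observed set itself) count as ties and
    enter neither tail.
    """
    uni, r, s_obs, m = _resolve_universe(gene_set, profile, trait, universe)
    if m == len(uni):
        warnings.warn(
            f"gene set covers the whole universe for trait {trait!r}; degenerate test"
        )
        return SkewnessTestResult(
            gene_set=gene_set_name, trait=trait, S=s_obs, n_genes_used=m, B=B,
            p_upper=0.0, p_lower=0.0, degenerate=True,
        )
    rng = np.random.default_rng(seed)
    tol = _tie_tol(s_obs)
    n_hi = 0
    n_lo = 0
    done = 0
    while done < B:
        nb = min(_PERM_CHUNK, B - done)
        # smallest m of iid uniforms = uniform random m-subset
        keys = rng.random((nb, len(uni)))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        s_b = r[idx].sum(axis=1)
        n_hi += int((s_b > s_obs + tol).sum())
        n_lo += int((s_b < s_obs - tol).sum())
        done += nb
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SkewnessTestResult(
        gene_set=gene_set_name, trait=trait, S=s_obs, n_genes_used=m, B=B,
        p_upper=n_hi / B, p_lower=n_lo / B, seed=seed_val,
    )


def exhaustive_null(
    gene_set,
    profile: CorrelationProfile,
    trait: str,
    universe=None,
    max_subsets: int = 10**6,
    gene_set_name: str = "gene_set",
) -> SkewnessTestResult:
    """Exact permutation tail by enumerating every size-m subset.

    Oracle counterpart of :func:`permutation_test` for small universes;
    refuses to enumerate more than ``max_subsets`` subsets.
    """
    uni, r, s_obs, m = _resolve_universe(gene_set, profile, trait, universe)
    from math import comb

    n_total = comb(len(uni), m)
    if n_total > max_subsets:
        raise ValueError(
            f"C({len(uni)}, {m}) = {n_total} exceeds max_subsets={max_subsets}; "
            "use permutation_test instead"
        )
    if m == len(uni):
        warnings.warn("gene set covers the whole universe; degenerate exact test")
        return SkewnessTestResult(
            gene_set=gene_set_name, trait=trait, S=s_obs, n_genes_used=m,
            B=1, p_upper=0.0, p_lower=0.0, degenerate=True,
        )
    tol = _tie_tol(s_obs)
    n_hi = n_lo = 0
    for combo in itertools.combinations(r, m):
        s_b = float(np.sum(combo))
        if s_b > s_obs + tol:
            n_hi += 1
        elif s_b < s_obs - tol:
            n_lo += 1
    return SkewnessTestResult(
        gene_set=gene_set_name, trait=trait, S=s_obs, n_genes_used=m, B=n_total,
        p_upper=n_hi / n_total, p_lower=n_lo / n_total,
    )


def run_trait_panel(
    gene_sets: dict[str, list[str]],
    data: BulkTraitDataset,
    B: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "pearson",
    universe=None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run the permutation test over the full gene-set x trait grid.

    One master seed spawns an independent, deterministic substream per
    (set, trait) cell, so any single cell can be reproduced in isolation.
    Failed cells (e.g. a set with no valid genes for a trait) become
    flagged rows rather than aborting the panel.  Significance is flagged
    at raw ``p < alpha`` on either tail (``bh_correct=True`` switches to
    Benjamini-Hochberg within each tail across the grid).
    """
    profile = gene_trait_correlations(data, method=method)
    rows = []
    for i, (name, genes) in enumerate(sorted(gene_sets.items())):
        for j, trait in enumerate(data.traits.columns):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(i, j))
            try:
                res = permutation_test(
                    genes, profile, trait, universe=universe, B=B,
                    seed=child, gene_set_name=name,
                )
                rows.append(
                    {
                        "set": name, "trait": trait, "m": res.n_genes_used,
                        "S": res.S, "B": res.B, "p_upper": res.p_upper,
                        "p_lower": res.p_lower, "degenerate": res.degenerate,
                        "error": "",
                    }
                )
            except ValueError as exc:
                rows.append(
                    {
                        "set": name, "trait": trait, "m": 0, "S": np.nan,
                        "B": B, "p_upper": np.nan, "p_lower": np.nan,
                        "degenerate": False, "error": str(exc),
                    }
                )
    table = pd.DataFrame(rows)
    ok = table["error"] == ""
    if bh_correct and ok.any():
        for col in ("p_upper", "p_lower"):
            adj = np.full(len(table), np.nan)
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, col].to_numpy(), method="fdr_bh"
            )[1]
            table[col + "_adj"] = adj
        table["significant"] = ok & (
            (table["p_upper_adj"] < alpha) | (table["p_lower_adj"] < alpha)
        )
    else:
        table["significant"] = ok & (
            (table["p_upper"] < alpha) | (table["p_lower"] < alpha)
        )
    return table
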