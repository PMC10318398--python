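"""Cluster gene signatures, per-cell module scores, and trajectory-origin
inference.

A cluster's signature is the top differentially expressed genes of that
cluster versus the rest.  Per-cell *module scores* follow the
binned-control scheme standard in the single-cell ecosystem (the
Tirosh / AddModuleScore family): the score is the mean normalized
expression of the signature genes minus the mean of a control gene set,
where controls are drawn, seeded, from the same average-expression bins as
the signature genes.  This centres the score at zero for a random gene
set, so enrichment of a centre-cluster signature can be compared across
the clusters of a differentiation trajectory.

The origin of a trajectory (an ordered chain of clusters, e.g.
F1 -> F2 -> F3 -> F4) is called *supported* for a candidate cluster when
the mean score of the candidate's signature decays monotonically from the
candidate to the terminus; per-step one-sided rank-sum tests are reported
as evidence rather than a hard p cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats


@dataclass
class GeneSignature:
    """A named, ordered, duplicate-free gene set."""

    name: str
    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ModuleScoreParams:
    n_bins: int = 25
    controls_per_gene: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.controls_per_gene < 1:
            raise ValueError("controls_per_gene must be >= 1")


@dataclass(frozen=True)
class TrajectoryTopology:
    """Ordered cluster chain from candidate origin to terminus."""

    trajectory_id: str
    clusters: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.clusters)) != len(self.clusters):
            raise ValueError("trajectory clusters must be unique")

    def reversed(self) -> "TrajectoryTopology":
        return TrajectoryTopology(self.trajectory_id + "_rev", self.clusters[::-1])


# ---------------------------------------------------------------------------
# signature construction
# ---------------------------------------------------------------------------

def rank_up_genes(
    de: pd.DataFrame,
    max_adjusted_p: float = 0.05,
    min_log2fc: float = 0.25,
    min_pct_group1: float = 0.25,
) -> pd.DataFrame:
    """Filter a DE table to significantly up-in-group1 genes and rank them.

    Ordering is adjusted p ascending, then |log2FC| descending, then gene
    symbol — fully deterministic under ties.
    """
    passing = de[
        (de["p_adj"] <= max_adjusted_p)
        & (de["log2fc"] >= min_log2fc)
        & (de["pct1"] >= min_pct_group1)
    ].copy()
    passing["_abs_lfc"] = passing["log2fc"].abs()
    passing = passing.sort_values(
        ["p_adj", "_abs_lfc", "gene"], ascending=[True, False, True]
    )
    return passing.drop(columns="_abs_lfc")


def build_cluster_signature(
    de_vs_rest: pd.DataFrame,
    cluster: str,
    top_n: int = 50,
    max_adjusted_p: float = 0.05,
    min_log2fc: float = 0.25,
    min_pct_group1: float = 0.25,
) -> GeneSignature:
    """Signature of a cluster from its one-vs-rest DE table.

    Takes the ``top_n`` significantly up genes; if fewer pass, returns all
    of them with a warning.
    """
    ranked = rank_up_genes(
        de_vs_rest,
        max_adjusted_p=max_adjusted_p,
        min_log2fc=min_log2fc,
        min_pct_group1=min_pct_group1,
    )
    genes = ranked["gene"].tolist()[:top_n]
    if len(genes) < top_n:
        warnings.warn(
            f"cluster {cluster!r}: only {len(genes)} of {top_n} requested "
            "signature genes pass the thresholds"
        )
    return GeneSignature(
        name=str(cluster), genes=genes, provenance=f"top-{top_n} DE of cluster {cluster}"
    )


# ---------------------------------------------------------------------------
# module score
# ---------------------------------------------------------------------------

def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def module_score(
    normalized: ad.AnnData,
    signature: GeneSignature,
    params: ModuleScoreParams = ModuleScoreParams(),
    return_controls: bool = False,
):
    """Binned-control module score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of average
    expression; for each signature gene, ``controls_per_gene`` control
    genes are sampled (seeded) from its bin, and the score is the mean
    expression of the signature genes minus the mean over the pooled
    control draws.  Signature genes absent from the matrix are dropped
    with a warning; an entirely absent signature is an error.  Scores are
    invariant to the order the signature genes are given in.
    """
    present = [g for g in signature.genes if g in normalized.var_names]
    missing = len(signature.genes) - len(present)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {missing} genes absent from the matrix"
        )

    X = normalized.X
    X = X.tocsc() if sparse.issparse(X) else np.asarray(X)
    avg = np.asarray(X.mean(axis=0)).ravel()
    # equal-frequency bins: rank-based cut, ties broken by position
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(normalized.n_vars, dtype=int)
    bin_of[order] = np.arange(normalized.n_vars) * params.n_bins // normalized.n_vars

    var_index = {g: j for j, g in enumerate(normalized.var_names)}
    bins: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)
    }
    rng = np.random.default_rng(params.seed)
    control_idx: list[np.ndarray] = []
    for g in sorted(present):  # sorted: order-invariance of the draw
        pool = bins[bin_of[var_index[g]]]
        take = min(params.controls_per_gene, pool.size)
        control_idx.append(rng.choice(pool, size=take, replace=False))
    controls = np.concatenate(control_idx)

    sig_cols = np.array([var_index[g] for g in present])
    sig_mean = np.asarray(X[:, sig_cols].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, controls].mean(axis=1)).ravel()
    scores = pd.Series(
        sig_mean - ctrl_mean, index=normalized.obs_names, name=signature.name
    )
    if return_controls:
        return scores, [str(normalized.var_names[j]) for j in controls]
    return scores


# ---------------------------------------------------------------------------
# origin inference
# ---------------------------------------------------------------------------

@dataclass
class OriginAssessment:
    """Verdict on a candidate origin cluster for one trajectory.

    ``supported`` requires strictly decreasing mean signature score from
    the candidate origin to the terminus; ``steps`` holds the per-step
    mean difference and one-sided rank-sum p-value as evidence.
    """

    trajectory_id: str
    candidate: str
    verdict: str  # "supported" | "ambiguous"
    cluster_means: pd.Series
    steps: pd.DataFrame = field(repr=False)


def infer_origin(
    scores: pd.Series,
    topology: TrajectoryTopology,
    cluster_labels: pd.Series,
) -> OriginAssessment:
    """Assess whether the first cluster of ``topology`` is the trajectory's
    origin, given per-cell scores of that cluster's signature.

    The candidate is ``supported`` iff the mean score strictly decreases
    at every step along the chain; otherwise ``ambiguous``.  Each step also
    carries a one-sided rank-sum p (earlier cluster > later cluster).
    """
    if len(topology.clusters) < 2:
        raise ValueError("trajectory must contain at least 2 clusters")
    labels = cluster_labels.reindex(scores.index)
    missing = [c for c in topology.clusters if c not in set(labels.dropna())]
    if missing:
        raise ValueError(f"clusters absent from labels: {missing}")

    groups = {c: scores[labels == c].to_numpy() for c in topology.clusters}
    means = pd.Series(
        {c: float(v.mean()) if v.size else np.nan for c, v in groups.items()},
        name="mean_score",
    )
    rows = []
    monotone = True
    for a, b in zip(topology.clusters[:-1], topology.clusters[1:]):
        va, vb = groups[a], groups[b]
        diff = float(va.mean() - vb.mean())
        if diff <= 0:
            monotone = False
        if va.size and vb.size and (np.ptp(np.concatenate([va, vb])) > 0):
            p = float(stats.mannwhitneyu(va, vb, alternative="greater").pvalue)
        else:
            p = 1.0
        rows.append({"from": a, "to": b, "mean_diff": diff, "p_greater": p})
    return OriginAssessment(
        trajectory_id=topology.trajectory_id,
        candidate=topology.clusters[0],
        verdict="supported" if monotone else "ambiguous",
        cluster_means=means,
        steps=pd.DataFrame(rows),
    )
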