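"""Fibroblast-vs-mural marker discovery with cross-dataset replication.

Differential expression between two cell populations uses the two-sided
Wilcoxon rank-sum test on log-normalized expression (the default test
family of the single-cell ecosystem): exact enumeration when both groups
have at most 8 cells and no ties, the tie-corrected normal approximation
otherwise.  Fold changes are computed on back-transformed (expm1) means
with a pseudocount of 1, p-values are Benjamini–Hochberg adjusted across
all tested genes.

Candidate markers are the significantly up-in-fibroblast genes capped at
a top-k (the candidate panel); replication then keeps only markers that
are significantly up in fibroblasts in *every* additional dataset,
operationalizing a candidate-panel -> validated-panel narrowing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .signature_scoring import GeneSignature, rank_up_genes

EXACT_MAX_GROUP = 8  # exact rank-sum enumeration up to this group size


@dataclass(frozen=True)
class MarkerCriteria:
    """Selection thresholds for calling a gene a marker."""

    max_adjusted_p: float = 0.05
    min_log2fc: float = 0.25
    min_pct_group1: float = 0.25
    top_k: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.max_adjusted_p <= 1:
            raise ValueError("max_adjusted_p must be in (0, 1]")
        if self.min_log2fc < 0 or not 0 <= self.min_pct_group1 <= 1:
            raise ValueError("invalid fold-change or detection-fraction threshold")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)


def wilcoxon_de(
    normalized: ad.AnnData,
    labels,
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two labelled groups.

    Returns a DataFrame with one row per gene: ``gene``, ``log2fc``
    (group1 over group2, pseudocount 1 on expm1-backtransformed means),
    ``p``, ``p_adj`` (BH over all genes), ``pct1``/``pct2`` (detection
    fractions), ``direction``.
    """
    labels = pd.Series(np.asarray(labels), index=normalized.obs_names)
    m1 = (labels == group1).to_numpy()
    m2 = (labels == group2).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError(
            f"both groups need >= 3 cells (got {int(m1.sum())} {group1!r}, "
            f"{int(m2.sum())} {group2!r})"
        )
    X = _dense(normalized.X)
    x1, x2 = X[m1], X[m2]
    n1, n2 = x1.shape[0], x2.shape[0]

    mean1 = np.expm1(x1).mean(axis=0)
    mean2 = np.expm1(x2).mean(axis=0)
    log2fc = np.log2(mean1 + 1.0) - np.log2(mean2 + 1.0)
    pct1 = (x1 > 0).mean(axis=0)
    pct2 = (x2 > 0).mean(axis=0)

    constant = np.ptp(np.vstack([x1, x2]), axis=0) == 0
    pvals = np.ones(X.shape[1])
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        for j in np.flatnonzero(~constant):
            a, b = x1[:, j], x2[:, j]
            method = "exact" if np.unique(np.r_[a, b]).size == n1 + n2 else "asymptotic"
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method=method).pvalue
    else:
        live = ~constant
        if live.any():
            res = stats.mannwhitneyu(
                x1[:, live], x2[:, live], alternative="two-sided",
                method="asymptotic", axis=0,
            )
            pvals[live] = np.atleast_1d(res.pvalue)
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": np.asarray(normalized.var_names),
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "pct1": pct1,
            "pct2": pct2,
            "direction": np.where(log2fc >= 0, "up_in_group1", "up_in_group2"),
        }
    )


def select_markers(
    de: pd.DataFrame, criteria: MarkerCriteria = MarkerCriteria(), name: str = "markers"
) -> GeneSignature:
    """Candidate marker panel: significant up-in-group1 genes, ranked by
    adjusted p then |log2FC| (symbol tie-break), capped at ``top_k``."""
    if de.empty:
        warnings.warn("empty DE table; empty marker signature")
        return GeneSignature(name=name, genes=[], provenance="empty DE input")
    ranked = rank_up_genes(
        de,
        max_adjusted_p=criteria.max_adjusted_p,
        min_log2fc=criteria.min_log2fc,
        min_pct_group1=criteria.min_pct_group1,
    )
    genes = ranked["gene"].tolist()[: criteria.top_k]
    if not genes:
        warnings.warn("no gene passes the marker criteria; empty signature")
    return GeneSignature(
        name=name, genes=genes,
        provenance=f"top-{criteria.top_k} up-in-group1 DE markers",
    )


def cross_dataset_validate(
    signature: GeneSignature,
    datasets: list[tuple[ad.AnnData, "pd.Series | np.ndarray"]],
    group1: str,
    group2: str,
    criteria: MarkerCriteria = MarkerCriteria(),
) -> tuple[GeneSignature, pd.DataFrame]:
    """Keep only markers replicating in every additional dataset.

    A marker is retained iff in each dataset it is present and passes the
    same significance/fold-change/detection thresholds (no top-k cap) for
    being up in ``group1``.  Returns the narrowed signature plus an
    evidence table with per-dataset log2FC, adjusted p and verdict.
    """
    evidence = []
    passing_per_ds: list[set[str]] = []
    for d, (adata, labels) in enumerate(datasets):
        de = wilcoxon_de(adata, labels, group1, group2).set_index("gene")
        ranked = set(
            rank_up_genes(
                de.reset_index(),
                max_adjusted_p=criteria.max_adjusted_p,
                min_log2fc=criteria.min_log2fc,
                min_pct_group1=criteria.min_pct_group1,
            )["gene"]
        )
        ds_pass = set()
        for g in signature.genes:
            if g not in de.index:
                evidence.append({"gene": g, "dataset": d, "log2fc": np.nan,
                                 "p_adj": np.nan, "status": "absent"})
                continue
            ok = g in ranked
            if ok:
                ds_pass.add(g)
            evidence.append({
                "gene": g, "dataset": d,
                "log2fc": float(de.loc[g, "log2fc"]),
                "p_adj": float(de.loc[g, "p_adj"]),
                "status": "pass" if ok else "fail",
            })
        passing_per_ds.append(ds_pass)
    retained = [g for g in signature.genes if all(g in s for s in passing_per_ds)]
    return (
        GeneSignature(
            name=signature.name + "_validated",
            genes=retained,
            provenance=f"{signature.name} replicated in {len(datasets)} datasets",
        ),
        pd.DataFrame(evidence),
    )
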