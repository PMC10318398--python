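"""Cell-level QC, normalization, in-silico mesenchymal selection and purity
checks for adventitial single-cell count matrices.

The three quality rules remove (i) low-quality cells with fewer than 1500
detected genes or more than 15% mitochondrial reads and (ii) potential
doublets with more than 15 000 total UMIs.  Removal conditions are strict
inequalities, so cells sitting exactly on a threshold (1500 genes, 15%
mito, 15 000 UMIs) are kept; all three thresholds are configurable.
Mesenchymal cells are then selected in silico on Pdgfrb expression, and
purity of the sort is checked by the absence of macrophage (Cd68),
endothelial (Pecam1), neuronal (Rbfox3) and adipocyte (Adipoq) markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

MITO_PREFIX = "mt-"


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds; defaults follow the study's three rules."""

    min_genes_detected: int = 1500
    max_mito_fraction: float = 0.15
    max_umi_total: int = 15_000

    def __post_init__(self) -> None:
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be >= 0")
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.max_umi_total <= 0:
            raise ValueError("max_umi_total must be positive")


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def _mito_mask(adata: ad.AnnData, mito_genes=None) -> np.ndarray:
    """Mito genes by explicit list, then var['is_mito'], then 'mt-' prefix."""
    if mito_genes is not None:
        mito_genes = list(mito_genes)
        present = adata.var_names.isin(mito_genes)
        missing = set(mito_genes) - set(adata.var_names)
        if missing:
            warnings.warn(
                f"{len(missing)} mito genes absent from the matrix: "
                f"{sorted(missing)[:5]}..."
            )
        return np.asarray(present)
    if "is_mito" in adata.var:
        return adata.var["is_mito"].to_numpy(dtype=bool)
    return np.asarray(adata.var_names.str.lower().str.startswith(MITO_PREFIX))


def compute_qc_metrics(adata: ad.AnnData, mito_genes=None) -> pd.DataFrame:
    """Per-cell QC metrics: genes_detected, umi_total, mito_fraction.

    ``mito_fraction`` is mitochondrial UMIs over total UMIs; cells with a
    zero total get mito_fraction 0 and ``is_degenerate`` True.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = adata.X
    mito = _mito_mask(adata, mito_genes)
    if sparse.issparse(X):
        X = X.tocsr()
        genes_detected = X.getnnz(axis=1)
        umi_total = np.asarray(X.sum(axis=1)).ravel()
        mito_umi = np.asarray(X[:, mito].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        genes_detected = (X > 0).sum(axis=1)
        umi_total = X.sum(axis=1)
        mito_umi = X[:, mito].sum(axis=1)
    degenerate = umi_total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(degenerate, 0.0, mito_umi / np.maximum(umi_total, 1))
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "umi_total": umi_total.astype(int),
            "mito_fraction": mito_fraction,
            "is_degenerate": degenerate,
        },
        index=adata.obs_names,
    )


@dataclass
class QCFilterResult:
    """Partition of cells into kept / removed_low_quality / removed_doublet.

    ``table`` has one row per cell with the metrics, the decision, and a
    comma-joined list of every rule the cell violates.
    """

    kept: pd.Index
    removed_low_quality: pd.Index
    removed_doublet: pd.Index
    table: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.kept) + len(self.removed_low_quality) + len(self.removed_doublet)
        if n != len(self.table):
            raise AssertionError("QC partition does not cover all cells exactly once")


def apply_qc_filters(
    metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> QCFilterResult:
    """Partition cells by the three retention rules.

    A cell is kept iff genes_detected >= min_genes AND mito_fraction <=
    max_mito AND umi_total <= max_umi (boundary cells kept).  Cells over
    the UMI cap are classed as doublets even when they also fail a
    low-quality rule; every violated rule is recorded per cell.
    """
    low_genes = metrics["genes_detected"] < thresholds.min_genes_detected
    high_mito = metrics["mito_fraction"] > thresholds.max_mito_fraction
    high_umi = metrics["umi_total"] > thresholds.max_umi_total

    reasons = []
    for lg, hm, hu in zip(low_genes, high_mito, high_umi):
        r = []
        if lg:
            r.append("low_genes")
        if hm:
            r.append("high_mito")
        if hu:
            r.append("high_umi")
        reasons.append(",".join(r))

    decision = np.where(
        high_umi, "removed_doublet",
        np.where(low_genes | high_mito, "removed_low_quality", "kept"),
    )
    table = metrics.copy()
    table["decision"] = decision
    table["reasons"] = reasons
    return QCFilterResult(
        kept=metrics.index[decision == "kept"],
        removed_low_quality=metrics.index[decision == "removed_low_quality"],
        removed_doublet=metrics.index[decision == "removed_doublet"],
        table=table,
    )


def normalize_log(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Library-size normalize each cell to ``scale`` total UMIs, then log1p.

    Zero-total cells stay all-zero.  Returns a new AnnData with a dense or
    sparse float X matching the input's sparsity.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    X = adata.X
    if sparse.issparse(X):
        X = X.tocsr().astype(float)
        totals = np.asarray(X.sum(axis=1)).ravel()
        factors = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
        X = sparse.diags(factors) @ X
        X.data = np.log1p(X.data)
    else:
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        factors = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
        X = np.log1p(X * factors[:, None])
    out = ad.AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["normalization"] = {"scale": scale, "log1p": True}
    return out


def select_mesenchymal(
    normalized: ad.AnnData, gate_gene: str = "Pdgfrb", min_expr: float = 0.0
) -> ad.AnnData:
    """In-silico selection of mesenchymal cells on a gate gene.

    Keeps cells with normalized expression strictly above ``min_expr``
    (default 0: any nonzero count).  Errors if the gate gene is absent.
    """
    if gate_gene not in normalized.var_names:
        raise KeyError(f"gate gene {gate_gene!r} not present in the matrix")
    j = normalized.var_names.get_loc(gate_gene)
    expr = _dense(normalized.X[:, [j]]).ravel()
    keep = expr > min_expr
    if not keep.any():
        warnings.warn(f"no cells pass the {gate_gene!r} gate; empty selection")
    return normalized[keep].copy()


def purity_check(
    normalized: ad.AnnData,
    absence_markers=("Cd68", "Pecam1", "Rbfox3", "Adipoq"),
    max_positive_fraction: float = 0.01,
) -> pd.DataFrame:
    """Check that lineage-contamination markers are essentially absent.

    For each marker reports the fraction of cells with nonzero expression
    and a status: ``pass`` (fraction <= max_positive_fraction), ``fail``,
    or ``untestable`` (marker not in the matrix).
    """
    rows = []
    for marker in absence_markers:
        if marker not in normalized.var_names:
            rows.append({"marker": marker, "positive_fraction": np.nan,
                         "status": "untestable"})
            continue
        j = normalized.var_names.get_loc(marker)
        expr = _dense(normalized.X[:, [j]]).ravel()
        frac = float((expr > 0).mean())
        rows.append({
            "marker": marker,
            "positive_fraction": frac,
            "status": "pass" if frac <= max_positive_fraction else "fail",
        })
    return pd.DataFrame(rows).set_index("marker")
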