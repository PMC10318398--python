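import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from advenfib import SimConfig


def make_adata(X, genes=None, barcodes=None, mito=None, sparse_x=False):
    """Small AnnData from a dense array; mito is a list of mito gene names."""
    X = np.asarray(X)
    n, g = X.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(g)]
    barcodes = list(barcodes) if barcodes is not None else [f"c{i}" for i in range(n)]
    mito = set(mito or [])
    var = pd.DataFrame({"is_mito": [s in mito for s in genes]},
                       index=pd.Index(genes, name="gene"))
    Xm = sparse.csr_matrix(X) if sparse_x else X
    return ad.AnnData(X=Xm, obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
                      var=var)


def marker_study_config(**overrides) -> SimConfig:
    """Generator config for the marker-discovery sub-study: planted
    fibroblast markers only, no branch or origin programs."""
    base = dict(
        n_cells=1000, n_genes=2000, n_branches=0, branch_program_size=0,
        origin_program_size=0, logfc_markers=2.0, seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def qc_boundary_fixture():
    """Constructed count matrix with exactly known per-cell QC metrics.

    Cells (thresholds 1500 genes / 0.15 mito / 15000 UMI, strict removal):
      boundary  — 1500 genes, 15000 UMI, mito exactly 0.15  -> kept
      low_genes — 1499 genes                                 -> removed_low_quality
      high_mito — mito fraction 0.16                         -> removed_low_quality
      doublet   — 15001 UMI, genes/mito fine                 -> removed_doublet
      clean     — comfortably inside all three rules         -> kept
      empty     — all-zero                                   -> removed_low_quality
    """
    n_genes = 2100
    mito_genes = [f"mt-{j}" for j in range(50)]
    genes = mito_genes + [f"g{j}" for j in range(n_genes - 50)]

    def cell(n_detected, umi_total, mito_umi):
        v = np.zeros(n_genes, dtype=int)
        if n_detected == 0:
            return v
        v[0] = mito_umi  # one mito gene carries all mito counts
        rest = umi_total - mito_umi
        n_other = n_detected - 1
        v[50 : 50 + n_other] = 1
        v[50] += rest - n_other  # pile the remainder on one gene
        return v

    X = np.stack([
        cell(1500, 15_000, 2250),   # boundary: 2250/15000 = 0.15
        cell(1499, 10_000, 500),    # low genes
        cell(2000, 10_000, 1600),   # high mito: 0.16
        cell(1600, 15_001, 150),    # doublet: 15001 UMI (mito 150/15001 ~ 0.01)
        cell(1800, 9_000, 450),     # clean: mito 0.05
        cell(0, 0, 0),              # empty
    ])
    barcodes = ["boundary", "low_genes", "high_mito", "doublet", "clean", "empty"]
    expected = {
        "boundary": "kept",
        "low_genes": "removed_low_quality",
        "high_mito": "removed_low_quality",
        "doublet": "removed_doublet",
        "clean": "kept",
        "empty": "removed_low_quality",
    }
    return make_adata(X, genes=genes, barcodes=barcodes, mito=mito_genes), expected
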