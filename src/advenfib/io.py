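"""Plain-text I/O: 10x-style MTX bundles, TSV tables, gene lists.

An MTX bundle is a directory holding ``matrix.mtx`` (MatrixMarket
coordinate integer, genes x cells as in CellRanger output),
``features.tsv`` (gene symbol and an ``is_mito`` 0/1 flag, no header) and
``barcodes.tsv`` (one barcode per line).  All tables are TSV with a
header row; gene lists are one symbol per line.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

FLOAT_FMT = "%.10g"


def write_mtx_bundle(adata: ad.AnnData, path) -> None:
    """Write counts as a genes x cells MatrixMarket bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = X.tocoo().T if sparse.issparse(X) else sparse.coo_matrix(np.asarray(X).T)
    spio.mmwrite(str(path / "matrix.mtx"), X, field="integer")
    is_mito = (
        adata.var["is_mito"].astype(int)
        if "is_mito" in adata.var
        else pd.Series(0, index=adata.var_names)
    )
    pd.DataFrame({"symbol": adata.var_names, "is_mito": np.asarray(is_mito)}).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", header=False, index=False)


def read_mtx_bundle(path) -> ad.AnnData:
    """Read a genes x cells MTX bundle into a cells x genes AnnData.

    Dimension mismatches between the matrix header and the sidecar files
    are errors; duplicate gene symbols are disambiguated by ``-1``, ``-2``
    suffixes (originals kept in ``var['orig_symbol']``).
    """
    path = Path(path)
    for fn in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (path / fn).exists():
            raise FileNotFoundError(f"MTX bundle is missing {fn} in {path}")
    M = spio.mmread(str(path / "matrix.mtx")).tocsr()
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None)[0].astype(str).tolist()
    n_genes, n_cells = M.shape
    if len(feats) != n_genes:
        raise ValueError(
            f"matrix header says {n_genes} genes but features.tsv has {len(feats)} rows"
        )
    if len(barcodes) != n_cells:
        raise ValueError(
            f"matrix header says {n_cells} cells but barcodes.tsv has {len(barcodes)} rows"
        )
    symbols = feats[0].astype(str).tolist()
    is_mito = (
        feats[1].astype(bool).to_numpy()
        if feats.shape[1] > 1
        else np.zeros(n_genes, dtype=bool)
    )
    var = pd.DataFrame({"is_mito": is_mito, "orig_symbol": symbols})
    var.index = pd.Index(_dedupe(symbols), name="gene")
    return ad.AnnData(
        X=M.T.tocsr().astype(np.int32),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=var,
    )


def _dedupe(symbols: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """TSV with a fixed float format, for byte-reproducible outputs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gene_list(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_ortholog_map(table: pd.DataFrame, path) -> None:
    write_tsv(table[["mouse_symbol", "human_symbol"]], path, index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if not {"mouse_symbol", "human_symbol"}.issubset(t.columns):
        raise ValueError("ortholog map needs mouse_symbol and human_symbol columns")
    return t
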