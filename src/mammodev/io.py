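"""Reading and writing the standard on-disk formats.

Count matrices travel as 10x-style MTX triplets (matrix.mtx, barcodes.tsv,
features.tsv, optionally gzipped) or dense CSV; images as TIFF; tables as
CSV. Readers return the package's in-memory containers (AnnData, numpy
arrays, DataFrames).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "read_10x_dir",
    "write_10x_dir",
    "read_counts_csv",
    "read_mask",
    "read_stack",
    "write_stack",
]


def _find(d: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = d / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {d}")


def read_10x_dir(path: str | Path) -> ad.AnnData:
    """Read a 10x MTX triplet directory into an AnnData (cells x genes)."""
    d = Path(path)
    mat = sp.csr_matrix(mmread(_find(d, "matrix.mtx"))).T  # genes x cells on disk
    barcodes = pd.read_csv(_find(d, "barcodes.tsv"), header=None, sep="\t")[0]
    try:
        feat_path = _find(d, "features.tsv")
    except FileNotFoundError:
        feat_path = _find(d, "genes.tsv")
    features = pd.read_csv(feat_path, header=None, sep="\t")
    symbols = features[1] if features.shape[1] > 1 else features[0]
    return ad.AnnData(
        X=mat.astype(np.int32),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(symbols, name="gene")),
    )


def write_10x_dir(adata: ad.AnnData, path: str | Path) -> None:
    """Write counts as a 10x-style MTX triplet plus obs/var CSVs."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(str(d / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.obs_names).to_csv(
        d / "barcodes.tsv", index=False, header=False
    )
    pd.DataFrame({"id": adata.var_names, "symbol": adata.var_names}).to_csv(
        d / "features.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(d / "cells.csv")
    adata.var.to_csv(d / "genes.csv")


def read_counts_csv(path: str | Path) -> ad.AnnData:
    """Read a dense cells x genes CSV (first column = barcodes)."""
    df = pd.read_csv(path, index_col=0)
    return ad.AnnData(
        X=sp.csr_matrix(df.to_numpy(dtype=np.int32)),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )


def read_mask(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path)) > 0


def read_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path))


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, stack)
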