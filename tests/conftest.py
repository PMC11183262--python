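"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import anndata as ad

from mammodev.simulate import (
    BranchMovieSpec,
    BudImageSpec,
    LineageSimSpec,
    gen_branch_movie,
    gen_bud_image,
    gen_lineage_counts,
)


@pytest.fixture(scope="session")
def small_lineage():
    """Two-stage bifurcating simulation, small enough for fast unit tests."""
    spec = LineageSimSpec(
        n_cells_per_stage={"E13.5": 150, "P0": 250},
        n_genes=600,
        n_signature_genes=40,
        n_temporal_genes=80,
        seed=11,
    )
    return gen_lineage_counts(spec)


@pytest.fixture(scope="session")
def normalized_lineage(small_lineage):
    from mammodev.preprocess import normalize, qc_filter

    adata, truth = small_lineage
    return normalize(qc_filter(adata)), truth


@pytest.fixture(scope="session")
def bud():
    """Default-profile bud image (inner-biased vs outer-biased probes)."""
    spec = BudImageSpec(seed=5)
    return spec, *gen_bud_image(spec)


@pytest.fixture(scope="session")
def movie():
    spec = BranchMovieSpec(seed=3)
    return spec, *gen_branch_movie(spec)


def make_adata(counts: np.ndarray, genes=None, barcodes=None) -> ad.AnnData:
    """Tiny AnnData from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame(index=barcodes or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes or [f"g{j}" for j in range(g)]),
    )


def layer_adata(values: np.ndarray, layer="lognorm", genes=None) -> ad.AnnData:
    """AnnData with a prescribed normalized layer (counts set to match)."""
    values = np.asarray(values, dtype=float)
    a = make_adata(np.maximum(values, 0).round().astype(int), genes=genes)
    a.layers[layer] = values
    return a
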