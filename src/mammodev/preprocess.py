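"""Quality control, normalization, embedding, clustering and markers.

The workflow mirrors standard droplet scRNA-seq practice on embryonic
mammary tissue: cells are kept when they carry at least ``min_umi`` UMIs and
at most ``max_mito`` mitochondrial UMI fraction, genes when detected in at
least ``min_cells_per_gene`` retained cells; counts are normalized to
analytic Pearson residuals of a negative-binomial model (used for variable
gene ranking and PCA) alongside a log1p depth-normalized layer (used for
scoring, marker statistics and downstream smoothing); clustering is Leiden
modularity optimization on a kNN graph in PC space at resolution 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

import anndata as ad
import scanpy as sc

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize",
    "pca_embedding",
    "cluster_cells",
    "find_markers",
    "regress_cell_cycle",
    "is_mito",
    "LAYER_PEARSON",
    "LAYER_LOGNORM",
]

LAYER_PEARSON = "pearson"
LAYER_LOGNORM = "lognorm"
PEARSON_THETA = 100.0


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level quality thresholds.

    Defaults are the thresholds used for the embryonic mammary atlas:
    minimum 5000 UMIs per cell, maximum 6% mitochondrial UMIs, and genes
    detected in at least 3 cells.
    """

    min_umi: float = 5000
    max_mito: float = 0.06
    min_cells_per_gene: int = 3

    def validate(self) -> None:
        if self.min_umi < 0 or self.max_mito < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be >= 0")


def is_mito(gene_names) -> np.ndarray:
    """Mitochondrial flag by case-insensitive ``mt-`` prefix (mouse naming)."""
    return np.array([str(g).lower().startswith("mt-") for g in gene_names])


def _counts_dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X)


class AllCellsFilteredError(ValueError):
    """Raised when QC removes every cell; carries per-criterion counts."""

    def __init__(self, n_low_umi: int, n_high_mito: int, n_total: int):
        self.n_low_umi = n_low_umi
        self.n_high_mito = n_high_mito
        super().__init__(
            f"all {n_total} cells filtered: {n_low_umi} below the UMI threshold, "
            f"{n_high_mito} above the mitochondrial threshold"
        )


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()
) -> ad.AnnData:
    """Filter cells on depth and mitochondrial load, then sparse genes.

    Cells are retained iff ``total_umi >= min_umi`` and
    ``mito_fraction <= max_mito``; genes are retained when detected in at
    least ``min_cells_per_gene`` of the *retained* cells. Returns a new
    object; the input is not modified. ``obs`` gains ``total_umi`` and
    ``mito_fraction``, ``var`` gains ``is_mito`` and ``n_cells_detected``.
    """
    thresholds.validate()
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = is_mito(adata.var_names)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / total, 0.0)

    keep_cells = (total >= thresholds.min_umi) & (mito_frac <= thresholds.max_mito)
    if not keep_cells.any():
        raise AllCellsFilteredError(
            int((total < thresholds.min_umi).sum()),
            int((mito_frac > thresholds.max_mito).sum()),
            adata.n_obs,
        )

    out = adata[keep_cells].copy()
    out.obs["total_umi"] = total[keep_cells]
    out.obs["mito_fraction"] = mito_frac[keep_cells]

    detected = np.asarray((out.X > 0).sum(axis=0)).ravel()
    keep_genes = detected >= thresholds.min_cells_per_gene
    out = out[:, keep_genes].copy()
    out.var["is_mito"] = is_mito(out.var_names)
    out.var["n_cells_detected"] = detected[keep_genes]
    return out


def normalize(adata: ad.AnnData, theta: float = PEARSON_THETA) -> ad.AnnData:
    """Add normalized layers and a variable-gene ranking.

    ``layers["pearson"]`` holds analytic Pearson residuals of an NB model
    with per-cell depth offset and overdispersion ``theta``, clipped at
    ±sqrt(n_cells); per-gene residual variance is stored in
    ``var["pearson_residual_var"]`` for highly-variable-gene ranking.
    ``layers["lognorm"]`` holds log1p counts-per-10k, the layer used for
    signature scores, markers and pseudotime smoothing.
    """
    total = np.asarray(adata.X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError("zero-depth cell encountered; run qc_filter first")
    out = adata.copy()

    tmp = adata.copy()
    sc.experimental.pp.normalize_pearson_residuals(tmp, theta=theta)
    resid = np.asarray(tmp.X, dtype=np.float64)
    out.layers[LAYER_PEARSON] = resid
    out.var["pearson_residual_var"] = resid.var(axis=0)

    tmp = adata.copy()
    sc.pp.normalize_total(tmp, target_sum=1e4)
    sc.pp.log1p(tmp)
    lognorm = tmp.X.toarray() if sp.issparse(tmp.X) else np.asarray(tmp.X)
    out.layers[LAYER_LOGNORM] = lognorm.astype(np.float64)
    out.uns["normalization"] = {"theta": theta, "target_sum": 1e4}
    return out


def pca_embedding(
    adata: ad.AnnData, n_hvg: int = 2000, n_pcs: int = 15
) -> ad.AnnData:
    """PCA on the top-variance genes of the Pearson-residual layer.

    The highly variable genes are the ``n_hvg`` genes of largest residual
    variance; PCs use a deterministic sign convention: each component is
    oriented so its largest-magnitude gene loading is positive. Scores land
    in ``obsm["X_pca"]``, loadings in ``varm["PCs"]`` (HVG rows only,
    zero elsewhere), explained variance ratios in ``uns["pca"]``.
    """
    if LAYER_PEARSON not in adata.layers:
        raise ValueError("run normalize() first")
    n_hvg = min(n_hvg, adata.n_vars)
    if n_pcs > min(adata.n_obs, n_hvg):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_cells, n_hvg)")

    var_rank = np.argsort(-adata.var["pearson_residual_var"].to_numpy(), kind="stable")
    hvg_ix = np.sort(var_rank[:n_hvg])
    hvg_mask = np.zeros(adata.n_vars, dtype=bool)
    hvg_mask[hvg_ix] = True
    adata.var["highly_variable"] = hvg_mask

    from sklearn.decomposition import PCA

    mat = adata.layers[LAYER_PEARSON][:, hvg_ix]
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(mat)
    loadings = pca.components_  # n_pcs x n_hvg

    # orient each PC so its largest-|.| loading is positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1

    adata.obsm["X_pca"] = scores
    full_load = np.zeros((adata.n_vars, n_pcs))
    full_load[hvg_ix] = loadings.T
    adata.varm["PCs"] = full_load
    adata.uns["pca"] = {"variance_ratio": pca.explained_variance_ratio_}
    return adata


def cluster_cells(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on an unweighted kNN graph in PC space.

    Labels are 0-based consecutive integers ordered by decreasing cluster
    size; deterministic given ``seed``.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    n = embedding.shape[0]
    if n <= k_neighbors:
        warnings.warn(
            f"k_neighbors={k_neighbors} >= n_cells={n}; reducing to {max(1, n - 1)}"
        )
        k_neighbors = max(1, n - 1)

    adj = kneighbors_graph(embedding, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)  # mutual union -> undirected, unweighted
    sources, targets = adj.nonzero()
    keep = sources < targets
    g = igraph.Graph(
        n=n, edges=list(zip(sources[keep].tolist(), targets[keep].tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing size, ties by original label index
    sizes = pd.Series(labels).value_counts().sort_values(ascending=False)
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def find_markers(
    adata: ad.AnnData,
    labels: np.ndarray,
    min_fraction: float = 0.10,
    min_lfc: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    For every cluster, each gene is tested on the lognorm layer against all
    other cells; genes pass when their in-cluster detection fraction exceeds
    ``min_fraction`` and the natural-log fold change of mean expm1
    expression (pseudocount 1) exceeds ``min_lfc``. P values are BH-adjusted
    across genes within each cluster.
    """
    if LAYER_LOGNORM not in adata.layers:
        raise ValueError("run normalize() first")
    from statsmodels.stats.multitest import multipletests

    Y = adata.layers[LAYER_LOGNORM]
    labels = np.asarray(labels)
    rows = []
    for cl in np.unique(labels):
        in_mask = labels == cl
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {cl} has fewer than 2 cells; skipped")
            continue
        Yin, Yout = Y[in_mask], Y[~in_mask]
        frac_in = (Yin > 0).mean(axis=0)
        frac_out = (Yout > 0).mean(axis=0)
        mean_in = np.expm1(Yin).mean(axis=0)
        mean_out = np.expm1(Yout).mean(axis=0)
        lfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = stats.mannwhitneyu(
                Yin, Yout, axis=0, alternative="two-sided"
            )
        pvals = np.nan_to_num(pvals, nan=1.0)
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        passing = (frac_in > min_fraction) & (lfc > min_lfc)
        for j in np.flatnonzero(passing):
            rows.append(
                (
                    cl,
                    adata.var_names[j],
                    float(lfc[j]),
                    float(frac_in[j]),
                    float(frac_out[j]),
                    float(pvals[j]),
                    float(adj[j]),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "gene",
            "log_fold_change",
            "fraction_in_cluster",
            "fraction_out",
            "p_value",
            "adjusted_p",
        ],
    )
    return table.sort_values(
        ["cluster", "adjusted_p", "gene"], ignore_index=True
    )


def regress_cell_cycle(
    adata: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    layer: str = LAYER_LOGNORM,
    score_params=None,
) -> ad.AnnData:
    """Remove cell-cycle variation by per-gene OLS on S and G2/M scores.

    Scores are module scores of the two phase signatures; the corrected
    layer is the OLS residual plus intercept, i.e. expression with the
    fitted S/G2M contribution subtracted. A proliferation score from the
    packaged 13-gene proliferation signature is stored when those genes are
    present.
    """
    from .scores import ScoreParams, module_score
    from .signatures import load_packaged_signature

    if not s_genes or not g2m_genes:
        raise ValueError("S and G2/M gene lists must be non-empty")
    params = score_params or ScoreParams()
    adata.obs["S_score"] = module_score(adata, s_genes, params, layer=layer)
    adata.obs["G2M_score"] = module_score(adata, g2m_genes, params, layer=layer)

    Y = adata.layers[layer]
    D = np.column_stack(
        [
            np.ones(adata.n_obs),
            adata.obs["S_score"].to_numpy(),
            adata.obs["G2M_score"].to_numpy(),
        ]
    )
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    adata.layers["corrected"] = Y - D[:, 1:] @ beta[1:]
    adata.uns["cell_cycle_regression"] = {"layer": layer}

    prolif = load_packaged_signature("proliferation")
    present = [g for g in prolif.genes if g in adata.var_names]
    if present:
        adata.obs["proliferation_score"] = module_score(
            adata, present, params, layer=layer
        )
    return adata
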