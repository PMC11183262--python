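"""End-to-end lineage pipeline: QC → normalize → cluster → score → trajectory.

Mirrors the study design: cells are clustered within each developmental
stage (each timepoint is a separate capture), identity scores place every
cell in the (luminal, basal) score plane, the developmental axis is the
principal component most correlated with stage, and the MST over per-stage
cluster pseudo-bulks yields the basal and luminal differentiation paths
with per-cell pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import anndata as ad

from . import trajectory as tj
from .preprocess import (
    QCThresholds,
    cluster_cells,
    normalize,
    pca_embedding,
    qc_filter,
)
from .scores import ScoreParams, assign_identity_scores
from .signatures import GeneSignature

__all__ = ["LineagePipelineResult", "run_lineage_pipeline"]


@dataclass
class LineagePipelineResult:
    adata: ad.AnnData
    embedding: tj.Embedding3D
    tree: tj.PseudoBulkTree
    paths: list[tj.LineagePath]
    pseudotime: dict[str, pd.DataFrame]
    cluster_summary: pd.DataFrame
    root: object = None
    endpoints: dict = field(default_factory=dict)


def _dev_axis(adata: ad.AnnData, stage_order: list[str]) -> np.ndarray:
    """PC most correlated (Spearman) with stage rank; PC2 by construction
    in the study, selected by correlation here so the choice is explicit."""
    rank = (
        adata.obs["stage"]
        .map({s: i for i, s in enumerate(stage_order)})
        .to_numpy(dtype=float)
    )
    pcs = adata.obsm["X_pca"]
    rhos = [
        abs(stats.spearmanr(pcs[:, k], rank).statistic)
        for k in range(min(5, pcs.shape[1]))
    ]
    best = int(np.argmax(rhos))
    return pcs[:, best]


def run_lineage_pipeline(
    adata: ad.AnnData,
    basal_signature: GeneSignature,
    luminal_signature: GeneSignature,
    qc: QCThresholds = QCThresholds(),
    score_params: ScoreParams = ScoreParams(),
    n_hvg: int = 2000,
    n_pcs: int = 15,
    resolution: float = 0.8,
    k_neighbors: int = 20,
    seed: int = 0,
) -> LineagePipelineResult:
    """Run the full single-cell lineage analysis on a raw count matrix.

    ``adata.obs["stage"]`` must hold developmental stage labels. Clustering
    is per stage (labels ``"<stage>:<k>"``); the root is the largest
    earliest-stage cluster and the lineage endpoints are the final-stage
    clusters with the highest median basal and luminal scores.
    """
    if "stage" not in adata.obs:
        raise ValueError('adata.obs["stage"] is required')
    adata = qc_filter(adata, qc)
    adata = normalize(adata)
    adata = pca_embedding(adata, n_hvg=n_hvg, n_pcs=n_pcs)

    stage_order = sorted(adata.obs["stage"].unique(), key=tj.stage_sort_key)
    labels = np.empty(adata.n_obs, dtype=object)
    for stage in stage_order:
        ix = np.flatnonzero((adata.obs["stage"] == stage).to_numpy())
        sub = adata.obsm["X_pca"][ix]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub_labels = cluster_cells(
                sub, k_neighbors=k_neighbors, resolution=resolution, seed=seed
            )
        labels[ix] = [f"{stage}:{c}" for c in sub_labels]
    adata.obs["cluster"] = pd.Categorical(labels.astype(str))

    adata, summary = assign_identity_scores(
        adata, [basal_signature, luminal_signature], score_params
    )
    bas, lum = basal_signature.name, luminal_signature.name

    dev = _dev_axis(adata, stage_order)
    emb = tj.embed_3d(
        adata.obs,
        dev,
        adata.obs["stage"],
        adata.obs["cluster"],
        luminal_col=f"score_{lum}",
        basal_col=f"score_{bas}",
        stage_order=stage_order,
    )
    centers = tj.pseudobulk_centers(emb)
    tree = tj.build_mst(centers)

    first, last = stage_order[0], stage_order[-1]
    first_clusters = summary[summary.index.str.startswith(f"{first}:")]
    root = first_clusters["n_cells"].idxmax()
    last_clusters = summary[summary.index.str.startswith(f"{last}:")]
    if len(last_clusters) < 2:
        raise ValueError(
            f"final stage {last!r} yields {len(last_clusters)} cluster(s); "
            "cannot define two lineage endpoints"
        )
    basal_end = last_clusters[f"median_{bas}"].idxmax()
    luminal_end = last_clusters[f"median_{lum}"].idxmax()
    if basal_end == luminal_end:
        # degenerate annotation: pick the two most score-divergent clusters
        diff = last_clusters[f"median_{bas}"] - last_clusters[f"median_{lum}"]
        basal_end, luminal_end = diff.idxmax(), diff.idxmin()
    endpoints = {"basal": basal_end, "luminal": luminal_end}

    paths = tj.extract_lineage_paths(tree, root, endpoints)
    pseudotime = {p.name: tj.project_pseudotime(emb, p) for p in paths}
    return LineagePipelineResult(
        adata=adata,
        embedding=emb,
        tree=tree,
        paths=paths,
        pseudotime=pseudotime,
        cluster_summary=summary,
        root=root,
        endpoints=endpoints,
    )
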