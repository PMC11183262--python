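"""3D differentiation trajectory: embedding, pseudo-bulk MST, pseudotime.

Cells are placed in a 3D space whose first two axes are the luminal and
basal identity scores and whose third axis is a developmental-time proxy
(by default the principal component most correlated with embryo age).
Each cluster is reduced to a "pseudo-bulk": the coordinate-wise median of
its cells. A Euclidean minimum spanning tree over pseudo-bulks defines the
cluster-level topology; basal and luminal lineages are the unique tree
paths from the root (earliest-stage cluster) to the corresponding endpoint
clusters. Per-cell pseudotime is the arc-length from the root to the cell's
orthogonal projection onto the lineage polyline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Embedding3D",
    "PseudoBulkTree",
    "LineagePath",
    "embed_3d",
    "pseudobulk_centers",
    "build_mst",
    "extract_lineage_paths",
    "project_pseudotime",
    "stage_sort_key",
]

AXES = ["x_luminal", "x_basal", "y_dev"]


def stage_sort_key(stage: str):
    """Chronological key for developmental stage labels (E13.5 < ... < P0)."""
    s = str(stage)
    if s.upper().startswith("E"):
        try:
            return (0, float(s[1:]))
        except ValueError:
            return (2, s)
    if s.upper().startswith("P"):
        try:
            return (1, float(s[1:]))
        except ValueError:
            return (2, s)
    return (2, s)


@dataclass
class Embedding3D:
    """Per-cell 3D coordinates with cluster and stage labels."""

    coords: pd.DataFrame  # columns AXES, indexed by cell id
    cluster: pd.Series
    stage: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.coords[AXES].to_numpy()).all():
            raise ValueError("non-finite coordinates in embedding")


def embed_3d(
    scores: pd.DataFrame,
    dev_axis: np.ndarray,
    stage: pd.Series,
    cluster: pd.Series,
    luminal_col: str = "score_luminal",
    basal_col: str = "score_basal",
    scale: bool = True,
    stage_order: list[str] | None = None,
) -> Embedding3D:
    """Assemble the (luminal score, basal score, developmental axis) space.

    The developmental axis is flipped if needed so the earliest stage has
    the lowest mean value; each axis is optionally min–max scaled so score
    units and PC units are commensurate (recorded in ``meta``). The Spearman
    correlation between the axis and stage rank is reported in
    ``meta["stage_rho"]``.
    """
    for col in (luminal_col, basal_col):
        if col not in scores.columns:
            raise ValueError(f"missing score column {col!r}")
    dev = np.asarray(dev_axis, dtype=float).copy()
    stage = pd.Series(np.asarray(stage), index=scores.index)
    cluster = pd.Series(np.asarray(cluster), index=scores.index)

    order = stage_order or sorted(stage.unique(), key=stage_sort_key)
    rank = stage.map({s: i for i, s in enumerate(order)}).to_numpy(dtype=float)
    flipped = False
    rho = np.nan
    if len(order) < 2:
        warnings.warn("single stage: developmental axis orientation unchanged")
    else:
        first, last = order[0], order[-1]
        if dev[stage == first].mean() > dev[stage == last].mean():
            dev = -dev
            flipped = True
        rho = float(stats.spearmanr(dev, rank).statistic)

    coords = pd.DataFrame(
        {
            "x_luminal": scores[luminal_col].to_numpy(dtype=float),
            "x_basal": scores[basal_col].to_numpy(dtype=float),
            "y_dev": dev,
        },
        index=scores.index,
    )
    if scale:
        for ax in AXES:
            lo, hi = coords[ax].min(), coords[ax].max()
            if hi > lo:
                coords[ax] = (coords[ax] - lo) / (hi - lo)
    return Embedding3D(
        coords=coords,
        cluster=cluster,
        stage=stage,
        meta={"scaled": scale, "dev_axis_flipped": flipped, "stage_rho": rho,
              "stage_order": order},
    )


def pseudobulk_centers(emb: Embedding3D) -> pd.DataFrame:
    """Coordinate-wise median of each cluster's cells (the pseudo-bulks)."""
    grouped = emb.coords.groupby(emb.cluster.to_numpy(), observed=True).median()
    if grouped.isna().to_numpy().any():
        raise ValueError("empty cluster encountered")
    return grouped


@dataclass
class PseudoBulkTree:
    """Minimum spanning tree over pseudo-bulk centers."""

    centers: pd.DataFrame
    graph: nx.Graph

    @property
    def edges(self) -> list[tuple]:
        return [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]

    @property
    def leaves(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree[n] == 1]


def build_mst(centers: pd.DataFrame) -> PseudoBulkTree:
    """Euclidean MST over cluster centers.

    Ties between equal-weight edges are broken lexicographically on the
    (sorted) cluster-id pair, which makes the tree deterministic. Coincident
    centers are permitted (zero-length edge, warning).
    """
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 centers")
    nodes = list(centers.index)
    pts = centers.to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = sorted(range(len(nodes)), key=lambda i: str(nodes[i]))
    for a_pos in range(len(order)):
        for b_pos in range(a_pos + 1, len(order)):
            i, j = order[a_pos], order[b_pos]
            d = float(np.linalg.norm(pts[i] - pts[j]))
            g.add_edge(nodes[i], nodes[j], weight=d)
    # stable Kruskal: edges were added in lexicographic order, and the sort
    # on weight is stable, so equal-weight ties resolve lexicographically
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
    if any(d["weight"] == 0 for _, _, d in tree.edges(data=True)):
        warnings.warn("coincident pseudo-bulk centers: zero-length MST edge")
    return PseudoBulkTree(centers=centers, graph=tree)


@dataclass
class LineagePath:
    """Ordered root-to-endpoint path through the pseudo-bulk tree."""

    name: str
    clusters: list
    vertices: np.ndarray  # n x 3 polyline
    arc_length: np.ndarray  # cumulative, per vertex

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


def extract_lineage_paths(
    tree: PseudoBulkTree, root, endpoints: dict[str, object]
) -> list[LineagePath]:
    """Unique tree path from the root to each named endpoint cluster."""
    paths = []
    for name, end in endpoints.items():
        if end == root:
            raise ValueError(f"endpoint of lineage {name!r} equals the root")
        seq = nx.shortest_path(tree.graph, root, end)
        verts = tree.centers.loc[seq].to_numpy(dtype=float)
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        paths.append(
            LineagePath(name=name, clusters=list(seq), vertices=verts,
                        arc_length=arc)
        )
    return paths


def project_pseudotime(
    points: np.ndarray | pd.DataFrame | Embedding3D, path: LineagePath
) -> pd.DataFrame:
    """Project each cell onto the lineage polyline.

    Returns per cell the chosen segment, the pseudotime (arc-length from the
    root to the projected point, clamped to the path) and the orthogonal
    residual distance. Ties between equally distant segments resolve to the
    earlier segment.
    """
    if isinstance(points, Embedding3D):
        index = points.coords.index
        P = points.coords[AXES].to_numpy(dtype=float)
    elif isinstance(points, pd.DataFrame):
        index = points.index
        P = points.to_numpy(dtype=float)
    else:
        P = np.asarray(points, dtype=float)
        index = pd.RangeIndex(P.shape[0])
    if path.vertices.shape[0] < 2:
        raise ValueError("path must have at least 2 vertices")

    A = path.vertices[:-1]  # segment starts
    B = path.vertices[1:]
    AB = B - A
    L2 = (AB**2).sum(axis=1)
    L2 = np.where(L2 == 0, 1.0, L2)

    # cells x segments projection parameter, clamped to the segment
    t = np.einsum("csd,sd->cs", P[:, None, :] - A[None, :, :], AB) / L2
    t = np.clip(t, 0.0, 1.0)
    proj = A[None, :, :] + t[..., None] * AB[None, :, :]
    dist = np.linalg.norm(P[:, None, :] - proj, axis=2)

    seg = dist.argmin(axis=1)  # argmin takes the first (earlier) on ties
    rows = np.arange(P.shape[0])
    seg_len = np.sqrt((AB**2).sum(axis=1))
    pseudotime = path.arc_length[seg] + t[rows, seg] * seg_len[seg]
    return pd.DataFrame(
        {
            "segment": seg,
            "pseudotime": pseudotime,
            "residual": dist[rows, seg],
            "proj_x_luminal": proj[rows, seg, 0],
            "proj_x_basal": proj[rows, seg, 1],
            "proj_y_dev": proj[rows, seg, 2],
        },
        index=index,
    )
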