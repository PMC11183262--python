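"""Static figures: 3D trajectory, pattern heatmap, interaction dot plot."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_trajectory_3d", "plot_pattern_heatmap", "plot_interaction_dotplot"]


def plot_trajectory_3d(emb, tree, paths, out_path, max_cells=2000, seed=0):
    """Cells, pseudo-bulk centers, MST edges and lineage polylines in 3D."""
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    coords = emb.coords
    if len(coords) > max_cells:
        ix = np.random.default_rng(seed).choice(len(coords), max_cells, False)
        coords = coords.iloc[ix]
    ax.scatter(coords["x_luminal"], coords["x_basal"], coords["y_dev"],
               s=3, alpha=0.25, c="gray")
    C = tree.centers
    ax.scatter(C["x_luminal"], C["x_basal"], C["y_dev"], s=40, c="black")
    for a, b, _ in tree.edges:
        seg = C.loc[[a, b]]
        ax.plot(seg["x_luminal"], seg["x_basal"], seg["y_dev"],
                c="black", lw=0.8, alpha=0.6)
    for path, color in zip(paths, ("crimson", "royalblue", "seagreen")):
        v = path.vertices
        ax.plot(v[:, 0], v[:, 1], v[:, 2], c=color, lw=2.5, label=path.name)
    ax.set_xlabel("luminal score")
    ax.set_ylabel("basal score")
    ax.set_zlabel("developmental axis")
    ax.legend()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_pattern_heatmap(profiles, labels, out_path):
    """Genes x pseudotime heatmap, rows grouped by pattern."""
    order = labels.sort_values(kind="stable").index
    X = profiles.profiles.loc[order].to_numpy()
    X = (X - X.mean(1, keepdims=True)) / np.where(
        X.std(1, keepdims=True) == 0, 1, X.std(1, keepdims=True)
    )
    fig, ax = plt.subplots(figsize=(6, max(3, 0.06 * len(order))))
    im = ax.imshow(X, aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xlabel("pseudotime grid")
    ax.set_ylabel("genes (grouped by pattern)")
    bounds = np.flatnonzero(np.diff(labels.loc[order].to_numpy())) + 0.5
    for b in bounds:
        ax.axhline(b, color="black", lw=0.5)
    fig.colorbar(im, ax=ax, label="z-scored expression")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_interaction_dotplot(results, out_path, alpha=0.01):
    """Cluster-pair x LR-pair dot plot, dot size = -log10 p."""
    df = results.copy()
    df["pair"] = df["sender_cluster"].astype(str) + "→" + df[
        "receiver_cluster"
    ].astype(str)
    xs = {p: i for i, p in enumerate(sorted(df["pair"].unique()))}
    ys = {p: i for i, p in enumerate(sorted(df["pair_id"].unique()))}
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(xs)), max(3, 0.4 * len(ys)))
    )
    size = -np.log10(df["p_value"].to_numpy())
    ax.scatter(
        df["pair"].map(xs), df["pair_id"].map(ys), s=30 * size + 5,
        c=np.where(df["p_value"] < alpha, "crimson", "lightgray"),
    )
    ax.set_xticks(list(xs.values()), list(xs), rotation=90)
    ax.set_yticks(list(ys.values()), list(ys))
    ax.set_xlabel("sender → receiver")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
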