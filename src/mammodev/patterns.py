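"""Pseudotime expression patterns along a lineage.

Genes with the top 10% variance across a lineage's cells are smoothed
against pseudotime with a penalized cubic smoothing spline (smoothing
parameter chosen by generalized cross-validation) and evaluated on a
common grid; the standardized profiles are grouped by agglomerative
clustering (Euclidean distance, complete linkage) cut at ``k`` clusters —
five patterns describe the basal trajectory and seven the luminal one in
the embryonic mammary gland.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline

__all__ = [
    "SmoothedProfileMatrix",
    "select_top_variable",
    "gam_smooth",
    "cluster_patterns",
]


def select_top_variable(
    expr: pd.DataFrame, top_frac: float = 0.10
) -> list[str]:
    """Genes with the top ``top_frac`` variance across cells.

    ``expr`` is cells x genes (normalized values). Returns ``ceil(frac*n)``
    gene names ranked by decreasing variance, ties broken by gene symbol.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 cells to rank variance")
    if expr.shape[1] < 10:
        raise ValueError("need at least 10 genes")
    var = expr.var(axis=0, ddof=1)
    n_top = math.ceil(top_frac * expr.shape[1])
    ranked = sorted(expr.columns, key=lambda g: (-var[g], g))
    return ranked[:n_top]


@dataclass
class SmoothedProfileMatrix:
    """Genes x grid matrix of spline-smoothed expression."""

    profiles: pd.DataFrame  # index genes, columns grid positions
    grid: np.ndarray
    lineage: str = ""

    def __post_init__(self):
        if self.profiles.isna().to_numpy().any():
            raise ValueError("missing values in smoothed profiles")
        if not (np.diff(self.grid) > 0).all():
            raise ValueError("grid must be strictly increasing")


def _spline_basis(x: np.ndarray, n_basis: int, lo: float, hi: float) -> np.ndarray:
    """Cubic B-spline design matrix with knots at interior quantile positions."""
    degree = 3
    n_interior = n_basis - degree - 1
    interior = (
        np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else []
    )
    knots = np.concatenate(
        [[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    )
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, degree, extrapolate=True).toarray()


def gam_smooth(
    expr: pd.DataFrame,
    pseudotime: np.ndarray,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    n_basis: int = 6,
    lineage: str = "",
) -> SmoothedProfileMatrix:
    """Smooth each gene against pseudotime on a common grid.

    Each gene gets a penalized cubic regression spline (``n_basis`` B-spline
    basis functions, second-order difference penalty on the coefficients);
    the penalty weight is chosen per gene by generalized cross-validation
    over a log-spaced grid. Cells sharing a pseudotime are aggregated to
    their mean with multiplicity weights. The evaluation grid defaults to
    ``n_grid`` points spanning the observed pseudotime range.
    """
    t = np.asarray(pseudotime, dtype=float)
    if t.size != expr.shape[0]:
        raise ValueError("pseudotime length must match number of cells")
    xu, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    if xu.size < 2:
        raise ValueError("all cells share the same pseudotime")
    if grid is None:
        grid = np.linspace(t.min(), t.max(), n_grid)
    grid = np.asarray(grid, dtype=float)

    Y = expr.to_numpy(dtype=float)
    sums = np.zeros((xu.size, Y.shape[1]))
    np.add.at(sums, inv, Y)
    means = sums / counts[:, None]
    w = counts.astype(float)

    fitted = np.empty((Y.shape[1], grid.size))
    if xu.size <= n_basis:
        # too few distinct pseudotimes for the basis: linear interpolation
        for j in range(Y.shape[1]):
            fitted[j] = np.interp(grid, xu, means[:, j])
        profiles = pd.DataFrame(fitted, index=expr.columns, columns=grid)
        return SmoothedProfileMatrix(profiles=profiles, grid=grid, lineage=lineage)

    lo, hi = float(t.min()), float(t.max())
    B = _spline_basis(xu, n_basis, lo, hi)
    Bg = _spline_basis(grid, n_basis, lo, hi)
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    P = D.T @ D
    BtW = B.T * w
    BtWB = BtW @ B
    n_eff = w.sum()
    lambdas = np.logspace(-6, 6, 30)

    # precompute factorizations per lambda (shared across genes)
    solves = []
    for lam in lambdas:
        A = BtWB + lam * P
        Ainv = np.linalg.pinv(A)
        hat_diag_tr = float(np.trace(Ainv @ BtWB))  # tr(S) under weights
        solves.append((Ainv, hat_diag_tr))

    for j in range(Y.shape[1]):
        y = means[:, j]
        if np.allclose(y, y[0]):
            fitted[j] = y[0]
            continue
        best_gcv, best_coef = np.inf, None
        by = BtW @ y
        for (Ainv, tr_s), lam in zip(solves, lambdas):
            coef = Ainv @ by
            resid = y - B @ coef
            rss = float(w @ resid**2)
            denom = max(n_eff - tr_s, 1e-8)
            gcv = n_eff * rss / denom**2
            if gcv < best_gcv:
                best_gcv, best_coef = gcv, coef
        fitted[j] = Bg @ best_coef
    profiles = pd.DataFrame(fitted, index=expr.columns, columns=grid)
    return SmoothedProfileMatrix(profiles=profiles, grid=grid, lineage=lineage)


def cluster_patterns(
    profiles: SmoothedProfileMatrix,
    k: int,
    standardize: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group smoothed gene profiles into ``k`` temporal patterns.

    Profiles are z-scored across the grid (heatmap convention, switchable),
    clustered agglomeratively with Euclidean distance and complete linkage,
    and the tree is cut at ``k``. Pattern ids 1..k are ordered by the grid
    position of each pattern mean's maximum, so pattern 1 peaks earliest.
    Returns (gene -> pattern labels, pattern mean curves).
    """
    X = profiles.profiles.to_numpy(dtype=float)
    n_genes = X.shape[0]
    if k > n_genes:
        raise ValueError(f"k={k} exceeds number of genes {n_genes}")
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(f"{int(flat.sum())} flat profile(s) standardized to zero")
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd

    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order pattern ids by peak position of the pattern mean
    peak = {}
    for c in np.unique(raw):
        peak[c] = float(np.argmax(X[raw == c].mean(axis=0)))
    order = sorted(peak, key=lambda c: (peak[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[c] for c in raw], index=profiles.profiles.index, name="pattern"
    )
    means = pd.DataFrame(
        {p: X[labels.to_numpy() == p].mean(axis=0) for p in sorted(remap.values())},
        index=profiles.profiles.columns,
    ).T
    return labels, means
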