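"""smRNA-FISH quantification inside a mammary bud mask.

The pipeline mirrors section-based RNAscope analysis: watershed
segmentation of epithelial cells on the membrane-marker channel, transcript
detection as scale-space Laplacian-of-Gaussian maxima (sigma 1–2 px), per-cell
transcript counts and two-probe ratios rendered on a purple-to-yellow color
key, and a ring statistic that splits the bud into three concentric bands
(inner / middle / outer thirds of the normalized distance-to-boundary
transform) and compares per-ring transcript percentages between probes with
a two-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import h_minima
from skimage.segmentation import watershed

__all__ = [
    "BudImage",
    "CellLabelMap",
    "RingStats",
    "segment_bud_cells",
    "detect_spots",
    "per_cell_counts_and_ratio",
    "ring_map",
    "ring_stats",
]


@dataclass
class BudImage:
    """Named 2D channels plus the manually drawn bud outline mask."""

    channels: dict[str, np.ndarray]
    bud_mask: np.ndarray
    pixel_size_um: float = 1.0
    membrane_channel: str = "membrane"

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shape = self.bud_mask.shape
        for name, chan in self.channels.items():
            if chan.shape != shape:
                raise ValueError(f"channel {name!r} shape differs from mask")


@dataclass
class CellLabelMap:
    """Integer-labeled segmentation (0 = background), labels 1..n."""

    labels: np.ndarray
    cells: pd.DataFrame  # label, centroid_y, centroid_x, area_px


def segment_bud_cells(
    img: BudImage,
    smoothing_sigma: float = 1.5,
    h_frac: float = 0.10,
    min_area_px: int = 30,
) -> CellLabelMap:
    """Watershed cells on the membrane channel inside the bud mask.

    Seeds are h-minima of the Gaussian-smoothed membrane intensity (depth
    ``h_frac`` of the in-mask intensity range); the watershed floods the
    smoothed intensity restricted to the mask. Regions smaller than
    ``min_area_px`` are merged into the neighbor sharing the longest
    boundary, and labels are renumbered consecutively from 1.
    """
    mask = img.bud_mask.astype(bool)
    if not mask.any():
        raise ValueError("empty bud mask")
    membrane = img.channels[img.membrane_channel].astype(float)
    smoothed = ndi.gaussian_filter(membrane, smoothing_sigma)

    vals = smoothed[mask]
    rng_int = vals.max() - vals.min()
    if rng_int == 0:
        labels = mask.astype(int)
    else:
        work = smoothed.copy()
        work[~mask] = vals.max() + rng_int  # keep minima inside the mask
        seeds = h_minima(work, h=h_frac * rng_int)
        markers, n_seeds = ndi.label(seeds & mask)
        if n_seeds == 0:
            labels = mask.astype(int)
        else:
            labels = watershed(smoothed, markers=markers, mask=mask)
    labels = _merge_small_regions(labels, min_area_px)
    labels = _relabel_consecutive(labels)

    cells = pd.DataFrame(
        [
            (p.label, p.centroid[0], p.centroid[1], p.area)
            for p in regionprops(labels)
        ],
        columns=["label", "centroid_y", "centroid_x", "area_px"],
    )
    return CellLabelMap(labels=labels, cells=cells)


def _merge_small_regions(labels: np.ndarray, min_area: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        if ids.size <= 1:
            break
        small = ids[areas < min_area]
        if small.size == 0:
            break
        merged_any = False
        for lab in small:
            region = labels == lab
            dil = ndi.binary_dilation(region)
            neighbors = labels[dil & ~region]
            neighbors = neighbors[neighbors > 0]
            if neighbors.size == 0:
                continue
            target, counts = np.unique(neighbors, return_counts=True)
            labels[region] = target[np.argmax(counts)]
            merged_any = True
        if not merged_any:
            break
    return labels


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels[labels > 0])
    remap = np.zeros(labels.max() + 1, dtype=int)
    remap[ids] = np.arange(1, ids.size + 1)
    return remap[labels]


def detect_spots(
    channel: np.ndarray,
    probe: str,
    min_sigma: float = 1.0,
    max_sigma: float = 2.0,
    n_scales: int = 5,
    threshold: str | float = "otsu",
    threshold_floor: float = 0.1,
) -> pd.DataFrame:
    """Scale-space LoG transcript detection on one probe channel.

    The channel is normalized to [0, 1] by its dtype range (integer images);
    float images are clipped at zero and divided by their maximum only when
    it exceeds 1, so a noise-only channel stays dim instead of being
    stretched to full scale.
    The scale-normalized negative Laplacian of Gaussian is evaluated on
    ``n_scales`` sigmas in [min_sigma, max_sigma]; 3D local maxima of the
    response cube above the threshold are kept, and maxima closer than
    sqrt(2)·sigma to a stronger one are merged away. The adaptive default
    threshold is Otsu on the positive responses with a noise floor of
    ``threshold_floor`` (fraction of the normalized dynamic range); pass an
    explicit float to override both.
    """
    chan = channel.astype(float)
    if np.issubdtype(channel.dtype, np.integer):
        chan = chan / np.iinfo(channel.dtype).max
    else:
        chan = np.clip(chan, 0.0, None)
        if chan.max() > 1.0:
            chan = chan / chan.max()
    if chan.max() == chan.min():
        return _empty_spots()

    sigmas = np.linspace(min_sigma, max_sigma, max(n_scales, 5))
    cube = np.stack(
        [-(s**2) * ndi.gaussian_laplace(chan, s) for s in sigmas]
    )
    if threshold == "otsu":
        pos = cube[cube > 0]
        if pos.size == 0:
            return _empty_spots()
        thr = max(float(threshold_otsu(pos)), threshold_floor)
    else:
        thr = float(threshold)

    local_max = cube == ndi.maximum_filter(cube, size=(3, 3, 3))
    cand = np.argwhere(local_max & (cube > thr))
    if cand.size == 0:
        return _empty_spots()
    responses = cube[cand[:, 0], cand[:, 1], cand[:, 2]]

    # greedy non-maximum suppression within sqrt(2)*sigma
    order = np.argsort(-responses, kind="stable")
    cand, responses = cand[order], responses[order]
    kept: list[int] = []
    tree_pts = cand[:, 1:].astype(float)
    tree = cKDTree(tree_pts)
    suppressed = np.zeros(cand.shape[0], dtype=bool)
    for i in range(cand.shape[0]):
        if suppressed[i]:
            continue
        kept.append(i)
        radius = np.sqrt(2.0) * sigmas[cand[i, 0]]
        for j in tree.query_ball_point(tree_pts[i], r=radius):
            if j != i:
                suppressed[j] = True

    rows = [
        (probe, int(cand[i, 1]), int(cand[i, 2]), float(sigmas[cand[i, 0]]),
         float(responses[i]))
        for i in kept
    ]
    return pd.DataFrame(rows, columns=["probe", "y", "x", "sigma", "response"])


def _empty_spots() -> pd.DataFrame:
    return pd.DataFrame(columns=["probe", "y", "x", "sigma", "response"])


def per_cell_counts_and_ratio(
    spots: pd.DataFrame,
    labelmap: CellLabelMap,
    probe_a: str,
    probe_b: str,
    cmap: str = "viridis",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell transcript counts and the A/(A+B) ratio map.

    Spots are assigned to the label under their (rounded) coordinates;
    cells with no transcript of either probe have an undefined ratio and
    render neutral gray. The ratio image colors each cell with a
    purple-to-yellow colormap from 0 (all probe B) to 1 (all probe A).
    """
    probes = set(spots["probe"].unique())
    for p in (probe_a, probe_b):
        if p not in probes:
            raise ValueError(f"unknown probe {p!r}; spots contain {sorted(probes)}")
    labels = labelmap.labels
    assigned = spots.copy()
    ys = assigned["y"].round().astype(int).clip(0, labels.shape[0] - 1)
    xs = assigned["x"].round().astype(int).clip(0, labels.shape[1] - 1)
    assigned["cell_label"] = labels[ys, xs]

    table = labelmap.cells[["label"]].copy()
    for name, probe in (("nA", probe_a), ("nB", probe_b)):
        sub = assigned[(assigned["probe"] == probe) & (assigned["cell_label"] > 0)]
        counts = sub.groupby("cell_label").size()
        table[name] = table["label"].map(counts).fillna(0).astype(int)
    total = table["nA"] + table["nB"]
    with np.errstate(invalid="ignore"):
        table["ratio"] = np.where(total > 0, table["nA"] / total, np.nan)

    import matplotlib

    colormap = matplotlib.colormaps[cmap]
    rgb = np.zeros(labels.shape + (3,), dtype=float)
    gray = (0.5, 0.5, 0.5)
    for _, row in table.iterrows():
        region = labels == row["label"]
        color = gray if np.isnan(row["ratio"]) else colormap(row["ratio"])[:3]
        rgb[region] = color
    return table, rgb


def ring_map(mask: np.ndarray, n_rings: int = 3) -> np.ndarray:
    """Ring index per pixel: 1 inner ... n_rings outer, 0 outside the mask.

    Rings are equal bands of the distance-to-boundary transform normalized
    by its maximum, so they are well defined for irregular bud outlines and
    partition the mask exactly.
    """
    mask = mask.astype(bool)
    edt = ndi.distance_transform_edt(mask)
    m = edt.max()
    if m == 0:
        return np.zeros(mask.shape, dtype=int)
    band = np.minimum((edt / m * n_rings).astype(int), n_rings - 1)
    return np.where(mask, n_rings - band, 0)


@dataclass
class RingStats:
    """Per-ring transcript percentages and the two-way ANOVA on them."""

    counts: pd.DataFrame  # replicate, probe, ring, count, percentage
    anova: pd.DataFrame
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)


RING_NAMES = {1: "inner", 2: "middle", 3: "outer"}


def ring_stats(
    spot_tables: list[pd.DataFrame],
    masks: list[np.ndarray],
    n_rings: int = 3,
) -> RingStats:
    """Ring-resolved transcript percentages with a two-way ANOVA.

    For each replicate (one spot table + bud mask), the percentage of each
    probe's transcripts per concentric ring is computed over the spots
    falling inside the mask; a fixed-effects two-way ANOVA (factors ring and
    probe, with interaction, type II sums of squares) tests whether probes
    distribute differently across rings, with Šidák-corrected per-ring
    probe contrasts.
    """
    if len(spot_tables) != len(masks) or not spot_tables:
        raise ValueError("need one mask per replicate and at least one replicate")
    rows = []
    for rep, (spots, mask) in enumerate(zip(spot_tables, masks)):
        rings = ring_map(mask, n_rings)
        ys = spots["y"].round().astype(int).clip(0, mask.shape[0] - 1)
        xs = spots["x"].round().astype(int).clip(0, mask.shape[1] - 1)
        ring_ix = rings[ys, xs]
        inside = ring_ix > 0
        if not inside.any():
            warnings.warn(f"replicate {rep}: no spots inside the mask; excluded")
            continue
        sub = spots.loc[inside.to_numpy() if hasattr(inside, "to_numpy") else inside]
        sub = sub.assign(ring=ring_ix[np.asarray(inside)])
        for probe, probe_spots in sub.groupby("probe"):
            total = len(probe_spots)
            per_ring = probe_spots.groupby("ring").size()
            for ring in range(1, n_rings + 1):
                count = int(per_ring.get(ring, 0))
                rows.append(
                    (rep, probe, ring, RING_NAMES.get(ring, str(ring)), count,
                     100.0 * count / total)
                )
    counts = pd.DataFrame(
        rows,
        columns=["replicate", "probe", "ring", "ring_name", "count", "percentage"],
    )
    if counts.empty:
        raise ValueError("no replicate contained spots inside its mask")

    anova = _two_way_anova(counts)
    contrasts = _sidak_ring_contrasts(counts, n_rings)
    return RingStats(counts=counts, anova=anova, contrasts=contrasts)


def _two_way_anova(counts: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if counts["probe"].nunique() < 2 or counts["replicate"].nunique() < 2:
        return pd.DataFrame()
    model = smf.ols("percentage ~ C(probe) * C(ring)", data=counts).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    return table.rename(
        index={
            "C(probe)": "probe",
            "C(ring)": "ring",
            "C(probe):C(ring)": "probe:ring",
            "Residual": "residual",
        }
    )


def _sidak_ring_contrasts(counts: pd.DataFrame, n_rings: int) -> pd.DataFrame:
    from scipy import stats as sps

    probes = sorted(counts["probe"].unique())
    if len(probes) != 2:
        return pd.DataFrame()
    a, b = probes
    rows = []
    for ring in range(1, n_rings + 1):
        xa = counts.query("probe == @a and ring == @ring")["percentage"]
        xb = counts.query("probe == @b and ring == @ring")["percentage"]
        if len(xa) < 2 or len(xb) < 2:
            continue
        t, p = sps.ttest_ind(xa, xb)
        p_adj = min(1.0, 1.0 - (1.0 - p) ** n_rings)
        rows.append((ring, RING_NAMES.get(ring, str(ring)), float(t), float(p),
                     float(p_adj)))
    return pd.DataFrame(
        rows, columns=["ring", "ring_name", "t", "p_value", "p_sidak"]
    )
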