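"""Synthetic data generators for every stage of the analysis.

Three generators emulate the three experimental data types the pipeline
consumes:

* :func:`gen_lineage_counts` — negative-binomial scRNA-seq counts over a
  Y-shaped basal/luminal lineage sampled at four developmental stages
  (E13.5, E14.5, E15.5, P0), with mitochondrial genes and injected
  low-quality cells so that QC is exercised.
* :func:`gen_bud_image` — a multi-channel mammary-bud section: a membrane
  channel with bright ridges on the boundaries of a Voronoi cell mosaic
  inside an elliptical bud mask, plus probe channels containing Gaussian
  transcript spots at controlled per-ring densities.
* :func:`gen_branch_movie` — a binary time-lapse mask stack of an explant
  body with branches whose tips advance at controlled velocities.

Each generator returns the synthetic dataset together with its ground truth
so recovery can be measured, and is fully deterministic given ``spec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint
from skimage.segmentation import find_boundaries

__all__ = [
    "LineageSimSpec",
    "LineageGroundTruth",
    "BudImageSpec",
    "BudGroundTruth",
    "BranchMovieSpec",
    "BranchGroundTruth",
    "gen_lineage_counts",
    "gen_bud_image",
    "gen_branch_movie",
    "DEFAULT_STAGE_WINDOWS",
    "N_MITO_GENES",
]

# Latent-time windows per developmental stage. The lineage is a Y: a single
# progenitor branch on t in [0, branch_point), two committed branches after.
DEFAULT_STAGE_WINDOWS: Mapping[str, tuple[float, float]] = {
    "E13.5": (0.00, 0.25),
    "E14.5": (0.20, 0.40),
    "E15.5": (0.35, 0.70),
    "P0": (0.70, 1.00),
}

N_MITO_GENES = 10


@dataclass(frozen=True)
class LineageSimSpec:
    """Parameters of the bifurcating-lineage count simulation.

    Defaults mirror the study conditions: the per-stage cell numbers equal
    the high-quality cell counts of the four sequenced timepoints, library
    size and dispersion are typical of 10x 3' data, and the signature
    divergence is 1.5 log2 units at full commitment.
    """

    n_cells_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"E13.5": 228, "E14.5": 59, "E15.5": 740, "P0": 409}
    )
    n_genes: int = 2000
    n_signature_genes: int = 50
    libsize_mean: float = 20_000.0
    nb_dispersion: float = 0.1
    effect_size: float = 1.5  # log2 divergence of lineage signatures
    mito_fraction: float = 0.03
    qc_fail_fraction: float = 0.05
    n_temporal_genes: int = 150
    temporal_amplitude: float = 1.5  # log2 swing of stage-dependent genes
    branch_point: float = 0.4
    stage_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_WINDOWS)
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells_per_stage:
            raise ValueError("n_cells_per_stage must not be empty")
        for stage, n in self.n_cells_per_stage.items():
            if n <= 0:
                raise ValueError(f"n_cells_per_stage[{stage!r}] must be > 0")
            if stage not in self.stage_windows:
                raise ValueError(f"no latent-time window for stage {stage!r}")
        if self.n_genes <= 0 or self.n_signature_genes <= 0:
            raise ValueError("gene counts must be > 0")
        reserved = 2 * self.n_signature_genes + self.n_temporal_genes + N_MITO_GENES
        if self.n_genes < reserved + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {reserved} structured genes"
            )
        if self.libsize_mean <= 0:
            raise ValueError("libsize_mean must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 < self.mito_fraction < 1.0:
            raise ValueError("mito_fraction must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.qc_fail_fraction < 1.0:
            raise ValueError("qc_fail_fraction must be in [0, 1)")


@dataclass
class LineageGroundTruth:
    """Latent variables behind a simulated count matrix."""

    cell_meta: pd.DataFrame  # latent_time, branch, qc_fail, stage
    basal_genes: list[str]
    luminal_genes: list[str]

    @property
    def signatures(self) -> dict[str, list[str]]:
        return {"basal": self.basal_genes, "luminal": self.luminal_genes}


def _commitment(t: np.ndarray, branch_point: float) -> np.ndarray:
    """Progression along a committed branch, 0 before the branch point."""
    return np.clip((t - branch_point) / (1.0 - branch_point), 0.0, None)


def gen_lineage_counts(
    spec: LineageSimSpec,
) -> tuple[ad.AnnData, LineageGroundTruth]:
    """Simulate NB counts over a bifurcating basal/luminal lineage.

    Returns an :class:`anndata.AnnData` with raw counts in ``X`` and stage
    labels in ``obs``, plus the ground truth (latent time, branch, signature
    gene lists, injected QC failures).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    basal_genes = [f"BasSig{i:03d}" for i in range(spec.n_signature_genes)]
    luminal_genes = [f"LumSig{i:03d}" for i in range(spec.n_signature_genes)]
    temporal_genes = [f"Dev{i:03d}" for i in range(spec.n_temporal_genes)]
    mito_genes = [f"mt-Sim{i}" for i in range(N_MITO_GENES)]
    n_filler = spec.n_genes - len(basal_genes) - len(luminal_genes) - len(
        temporal_genes
    ) - len(mito_genes)
    filler_genes = [f"Gene{i:04d}" for i in range(n_filler)]
    genes = basal_genes + luminal_genes + temporal_genes + mito_genes + filler_genes

    # Per-gene relative abundance, log-normal; mitochondrial genes are
    # rescaled per cell below so their expected UMI share is mito_fraction.
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    mito_ix = np.array([gene_idx[g] for g in mito_genes])

    # Latent cell states.
    stages, times, branches = [], [], []
    for stage, n in spec.n_cells_per_stage.items():
        lo, hi = spec.stage_windows[stage]
        t = rng.uniform(lo, hi, size=n)
        b = np.where(
            t > spec.branch_point,
            rng.choice(["basal", "luminal"], size=n),
            "early",
        )
        stages.extend([stage] * n)
        times.append(t)
        branches.append(b)
    t = np.concatenate(times)
    branch = np.concatenate(branches)
    stage_arr = np.array(stages)
    n_cells = t.size

    # log2 expression modifiers: lineage signatures diverge with commitment,
    # temporal program ramps with latent time (half up, half down).
    log2mod = np.zeros((n_cells, spec.n_genes))
    prog = _commitment(t, spec.branch_point)
    sign = np.where(branch == "basal", 1.0, np.where(branch == "luminal", -1.0, 0.0))
    bas_ix = np.array([gene_idx[g] for g in basal_genes])
    lum_ix = np.array([gene_idx[g] for g in luminal_genes])
    log2mod[:, bas_ix] = (spec.effect_size * prog * sign)[:, None]
    log2mod[:, lum_ix] = (-spec.effect_size * prog * sign)[:, None]
    tmp_ix = np.array([gene_idx[g] for g in temporal_genes])
    half = len(tmp_ix) // 2
    log2mod[:, tmp_ix[:half]] = (spec.temporal_amplitude * t)[:, None]
    log2mod[:, tmp_ix[half:]] = (spec.temporal_amplitude * (1.0 - t))[:, None]

    weights = base[None, :] * np.exp2(log2mod)
    # fix the expected mitochondrial UMI share to mito_fraction in every cell
    non_mito_sum = np.delete(weights, mito_ix, axis=1).sum(axis=1)
    mito_profile = base[mito_ix] / base[mito_ix].sum()
    weights[:, mito_ix] = (
        spec.mito_fraction / (1.0 - spec.mito_fraction)
    ) * non_mito_sum[:, None] * mito_profile[None, :]

    # Library sizes; a seeded subset of cells is injected with low depth or
    # high mitochondrial load to exercise QC.
    libsize = rng.lognormal(
        mean=math.log(spec.libsize_mean) - 0.5 * 0.25**2, sigma=0.25, size=n_cells
    )
    n_fail = int(round(spec.qc_fail_fraction * n_cells))
    fail_ix = rng.choice(n_cells, size=n_fail, replace=False)
    qc_fail = np.zeros(n_cells, dtype=bool)
    qc_fail[fail_ix] = True
    low_depth = fail_ix[: n_fail // 2]
    high_mito = fail_ix[n_fail // 2 :]
    libsize[low_depth] = rng.uniform(500.0, 4000.0, size=low_depth.size)
    if high_mito.size:
        target = rng.uniform(0.10, 0.25, size=high_mito.size)
        cur = weights[high_mito][:, mito_ix].sum(axis=1)
        other = weights[high_mito].sum(axis=1) - cur
        scale = target / (1.0 - target) * other / cur
        weights[np.ix_(high_mito, mito_ix)] *= scale[:, None]

    probs = weights / weights.sum(axis=1, keepdims=True)
    mean = libsize[:, None] * probs
    n_nb = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mean)).astype(np.int32)

    barcodes = [f"cell_{i:05d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"stage": pd.Categorical(stage_arr)}, index=barcodes),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = LineageGroundTruth(
        cell_meta=pd.DataFrame(
            {
                "latent_time": t,
                "branch": branch,
                "qc_fail": qc_fail,
                "stage": stage_arr,
            },
            index=barcodes,
        ),
        basal_genes=basal_genes,
        luminal_genes=luminal_genes,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# Bud images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BudImageSpec:
    """Parameters of the synthetic smFISH bud section.

    ``ring_density_profile`` maps ``(probe, ring)`` to the expected number of
    transcript spots per cell whose centroid falls in that ring; rings are
    numbered 1 (inner), 2 (middle), 3 (outer). The default profile places an
    inner-biased probe against an outer-biased probe, the configuration the
    ring statistic is designed to detect.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 150
    ring_density_profile: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("Anxa1", 1): 8.0,
            ("Anxa1", 2): 4.0,
            ("Anxa1", 3): 1.0,
            ("Cxcl14", 1): 1.0,
            ("Cxcl14", 2): 4.0,
            ("Cxcl14", 3): 8.0,
        }
    )
    spot_sigma_px: float = 1.5
    membrane_width_px: float = 2.0
    spot_amplitude: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    @property
    def probes(self) -> list[str]:
        return sorted({p for p, _ in self.ring_density_profile})

    def validate(self) -> None:
        if self.image_shape[0] < 64 or self.image_shape[1] < 64:
            raise ValueError("image_shape must be at least 64x64")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if any(d < 0 for d in self.ring_density_profile.values()):
            raise ValueError("ring densities must be >= 0")
        if self.spot_sigma_px <= 0 or self.membrane_width_px <= 0:
            raise ValueError("widths must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BudGroundTruth:
    """Cell mosaic and spot coordinates behind a synthetic bud image."""

    cell_labels: np.ndarray  # H x W int, 0 = outside bud
    bud_mask: np.ndarray  # H x W bool
    spots: pd.DataFrame  # probe, y, x, cell_label, ring_index
    cell_centers: np.ndarray  # n_cells x 2 (y, x)


def _ring_index_map(mask: np.ndarray, n_rings: int = 3) -> np.ndarray:
    """Ring index per pixel; shares its definition with the quantification."""
    from .fish import ring_map

    return ring_map(mask, n_rings)


def gen_bud_image(
    spec: BudImageSpec,
) -> tuple[dict[str, np.ndarray], BudGroundTruth]:
    """Render a membrane channel plus probe channels for a synthetic bud.

    Cells are the Voronoi regions of uniformly sampled centers inside an
    elliptical bud mask; the membrane channel carries Gaussian ridges on the
    cell boundaries; each probe channel carries Gaussian spots drawn per cell
    at the ring density of the cell's centroid ring.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.42 * h, 0.42 * w
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    inside = np.argwhere(mask)
    if spec.n_cells > inside.shape[0] // 25:
        raise ValueError(
            f"n_cells={spec.n_cells} too large for bud of {inside.shape[0]} px"
        )
    centers = inside[rng.choice(inside.shape[0], size=spec.n_cells, replace=False)]

    # Voronoi tessellation by nearest center, restricted to the mask.
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(centers).query(inside)
    labels = np.zeros((h, w), dtype=int)
    labels[inside[:, 0], inside[:, 1]] = nearest + 1

    membrane = find_boundaries(labels, mode="thick") & mask
    mem = gaussian_filter(
        membrane.astype(float), sigma=spec.membrane_width_px / 2.0
    )
    mem /= mem.max() if mem.max() > 0 else 1.0

    rings = _ring_index_map(mask)
    cell_ring = np.array([rings[cy_, cx_] for cy_, cx_ in centers])

    channels: dict[str, np.ndarray] = {}
    spot_rows: list[tuple] = []
    for probe in spec.probes:
        chan = np.zeros((h, w), dtype=float)
        probe_rows: list[tuple] = []
        for lab in range(1, spec.n_cells + 1):
            lam = spec.ring_density_profile.get((probe, int(cell_ring[lab - 1])), 0.0)
            n_spots = rng.poisson(lam)
            if n_spots == 0:
                continue
            pix = np.argwhere(labels == lab)
            if pix.size == 0:
                continue
            chosen = pix[rng.integers(0, pix.shape[0], size=n_spots)]
            for sy, sx in chosen:
                probe_rows.append(
                    (probe, int(sy), int(sx), lab, int(rings[sy, sx]))
                )
        spot_rows.extend(probe_rows)
        for _, sy, sx, _, _ in probe_rows:
            y0, y1 = max(0, sy - 6), min(h, sy + 7)
            x0, x1 = max(0, sx - 6), min(w, sx + 7)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            chan[y0:y1, x0:x1] += spec.spot_amplitude * np.exp(
                -((gy - sy) ** 2 + (gx - sx) ** 2) / (2 * spec.spot_sigma_px**2)
            )
        chan += rng.normal(0.0, spec.noise_sd, size=(h, w))
        channels[probe] = _to_uint16(chan, full_scale=2.0 * spec.spot_amplitude)

    membrane_img = mem + rng.normal(0.0, spec.noise_sd * 0.5, size=(h, w))
    channels = {"membrane": _to_uint16(membrane_img, full_scale=2.0), **channels}

    spots = pd.DataFrame(
        spot_rows, columns=["probe", "y", "x", "cell_label", "ring_index"]
    )
    truth = BudGroundTruth(
        cell_labels=labels, bud_mask=mask, spots=spots, cell_centers=centers
    )
    return channels, truth


def _to_uint16(img: np.ndarray, full_scale: float) -> np.ndarray:
    """Fixed-scale conversion: ``full_scale`` maps to the dtype maximum.

    A fixed scale (rather than per-image stretching) keeps noise-only
    channels dim, as on a real detector."""
    return np.clip(img / full_scale * 65535, 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# Branching movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchMovieSpec:
    """Parameters of the synthetic explant time-lapse.

    Each branch is a thick ray from a central body whose tip advances at its
    ``tip_velocity_um_per_h``; with the default calibration (1 µm/px, 60 min
    frames, 25 frames) the movie spans 24 h of growth, matching the imaging
    protocol the tracker is designed for.
    """

    n_frames: int = 25
    frame_interval_min: float = 60.0
    pixel_size_um: float = 1.0
    tip_velocity_um_per_h: Sequence[float] = (5.0, 10.0, 20.0)
    branch_width_px: int = 7
    image_shape: tuple[int, int] = (1100, 1100)
    body_radius_px: int = 16
    initial_length_px: float = 25.0
    seed: int = 0

    @property
    def n_branches(self) -> int:
        return len(self.tip_velocity_um_per_h)

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if any(v < 0 for v in self.tip_velocity_um_per_h):
            raise ValueError("velocities must be >= 0")
        if self.frame_interval_min <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibrations must be > 0")
        if self.n_branches == 0:
            raise ValueError("at least one branch required")
        if self.branch_width_px < 1:
            raise ValueError("branch_width_px must be >= 1")


@dataclass
class BranchGroundTruth:
    """True tip positions: frame x branch x (y, x)."""

    tip_positions: np.ndarray
    angles_rad: np.ndarray


def gen_branch_movie(
    spec: BranchMovieSpec,
) -> tuple[np.ndarray, BranchGroundTruth]:
    """Render a binary mask stack of branches elongating from a common body."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    base = 2 * np.pi * rng.uniform()
    angles = (base + 2 * np.pi * np.arange(spec.n_branches) / spec.n_branches) % (
        2 * np.pi
    )

    step_px = (
        np.asarray(spec.tip_velocity_um_per_h, dtype=float)
        * (spec.frame_interval_min / 60.0)
        / spec.pixel_size_um
    )
    final_len = spec.initial_length_px + step_px * (spec.n_frames - 1)
    max_extent = spec.body_radius_px + final_len.max() + spec.branch_width_px
    if max_extent >= min(h, w) / 2.0:
        raise ValueError(
            "tip leaves the frame: reduce velocity, frames, or increase image_shape"
        )

    foot = disk_footprint(spec.branch_width_px // 2)
    frames = np.zeros((spec.n_frames, h, w), dtype=bool)
    tips = np.zeros((spec.n_frames, spec.n_branches, 2))
    for f in range(spec.n_frames):
        frame = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((cy, cx), spec.body_radius_px, shape=(h, w))
        frame[rr, cc] = True
        for b, ang in enumerate(angles):
            length = spec.initial_length_px + step_px[b] * f
            ty = cy + length * np.sin(ang)
            tx = cx + length * np.cos(ang)
            rr, cc = draw_line(int(round(cy)), int(round(cx)), int(round(ty)),
                               int(round(tx)))
            frame[rr, cc] = True
            tips[f, b] = (ty, tx)
        frames[f] = dilation(frame, foot)
    return frames, BranchGroundTruth(tip_positions=tips, angles_rad=angles)
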