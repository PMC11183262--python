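"""Explant branching morphometrics: tip tracking, area, diameter, EdU.

Time-lapse mask stacks of ex vivo mammary explants are reduced to per-branch
tip trajectories: each frame's mask is skeletonized, skeleton endpoints
(pixels with exactly one 8-neighbor, away from the image border) are the
branch tips, and tips are linked greedily between consecutive frames under
a distance gate. Track velocity is the traveled path length divided by the
elapsed time. Endpoint morphometrics cover planar area (and its fold change
versus the first frame), branch count, branch base diameter from the
distance transform at the branch's junction with the main body, and the
EdU-positive nuclear fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, skeletonize

__all__ = [
    "MaskStack",
    "TipTrackSet",
    "Morphometrics",
    "segment_frames",
    "find_tips",
    "track_tips_velocity",
    "morphometrics",
    "edu_fraction",
]


@dataclass
class MaskStack:
    """T x H x W binary masks with physical calibration."""

    frames: np.ndarray
    frame_interval_min: float
    pixel_size_um: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames).astype(bool)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W stack with T >= 1")
        if self.frame_interval_min <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibrations must be > 0")


def segment_frames(
    images: np.ndarray,
    frame_interval_min: float,
    pixel_size_um: float,
    smoothing_sigma: float = 2.0,
    closing_radius: int = 2,
) -> MaskStack:
    """Threshold-segment grayscale frames into an explant mask stack.

    Gaussian smoothing, Otsu threshold, largest connected component,
    morphological closing. Boolean input is treated as pre-segmented masks
    and passed through unchanged (the bypass for external segmenters).
    """
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    if images.dtype == bool:
        return MaskStack(images, frame_interval_min, pixel_size_um)

    foot = disk(closing_radius) if closing_radius > 0 else None
    masks = np.zeros(images.shape, dtype=bool)
    for f, frame in enumerate(images):
        sm = ndi.gaussian_filter(frame.astype(float), smoothing_sigma)
        if sm.max() == sm.min():
            raise ValueError(f"frame {f}: empty foreground (constant image)")
        fg = sm > threshold_otsu(sm)
        lab, n = ndi.label(fg)
        if n == 0:
            raise ValueError(f"frame {f}: empty foreground after thresholding")
        sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
        if foot is not None:
            mask = closing(mask, foot)
        masks[f] = mask
    return MaskStack(masks, frame_interval_min, pixel_size_um)


def find_tips(mask: np.ndarray, border_px: int = 2) -> np.ndarray:
    """Skeleton endpoints of a binary mask, excluding the border margin.

    A tip is a skeleton pixel with exactly one 8-connected skeleton
    neighbor. Returns an n x 2 array of (y, x).
    """
    skel = skeletonize(mask.astype(bool))
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    neighbor_count = ndi.convolve(skel.astype(int), kernel, mode="constant")
    tips = skel & (neighbor_count == 1)
    if border_px > 0:
        tips[:border_px, :] = False
        tips[-border_px:, :] = False
        tips[:, :border_px] = False
        tips[:, -border_px:] = False
    return np.argwhere(tips)


@dataclass
class TipTrackSet:
    """Linked tip trajectories with per-track mean velocities."""

    tracks: pd.DataFrame  # track_id, frame, y, x
    velocities: pd.DataFrame  # track_id, n_frames, path_um, velocity_um_per_h
    meta: dict = field(default_factory=dict)


def track_tips_velocity(
    stack: MaskStack,
    max_link_um: float = 30.0,
    min_track_len: int = 3,
    border_px: int = 2,
) -> TipTrackSet:
    """Track skeleton tips across frames and measure their growth velocity.

    Tips in consecutive frames are linked greedily by increasing distance
    under the ``max_link_um`` gate; an unlinked tip opens a new track.
    Velocity is the total traveled path length (µm) over the track's elapsed
    time (h); tracks shorter than ``min_track_len`` frames are discarded.
    """
    if stack.frames.shape[0] < 2:
        raise ValueError("need at least 2 frames to track")
    px, dt_h = stack.pixel_size_um, stack.frame_interval_min / 60.0

    tracks: dict[int, list[tuple[int, float, float]]] = {}
    active: dict[int, tuple[float, float]] = {}
    next_id = 0
    for f, frame in enumerate(stack.frames):
        tips = find_tips(frame, border_px=border_px)
        if tips.size == 0:
            active = {}
            continue
        unmatched = set(range(len(tips)))
        if active:
            track_ids = list(active)
            prev = np.array([active[t] for t in track_ids])
            d = np.linalg.norm(
                prev[:, None, :] - tips[None, :, :].astype(float), axis=2
            ) * px
            order = np.argsort(d, axis=None, kind="stable")
            used_tracks: set[int] = set()
            for flat in order:
                i, j = np.unravel_index(flat, d.shape)
                if d[i, j] > max_link_um:
                    break
                if track_ids[i] in used_tracks or j not in unmatched:
                    continue
                tid = track_ids[i]
                tracks[tid].append((f, float(tips[j, 0]), float(tips[j, 1])))
                active[tid] = (float(tips[j, 0]), float(tips[j, 1]))
                used_tracks.add(tid)
                unmatched.discard(j)
            for tid in set(track_ids) - used_tracks:
                del active[tid]
        for j in sorted(unmatched):
            tracks[next_id] = [(f, float(tips[j, 0]), float(tips[j, 1]))]
            active[next_id] = (float(tips[j, 0]), float(tips[j, 1]))
            next_id += 1

    rows, vel_rows = [], []
    for tid, pts in tracks.items():
        if len(pts) < min_track_len:
            continue
        arr = np.array([(y, x) for _, y, x in pts])
        frames_ = [f for f, _, _ in pts]
        path_um = float(
            np.linalg.norm(np.diff(arr, axis=0), axis=1).sum() * px
        )
        hours = (frames_[-1] - frames_[0]) * dt_h
        vel_rows.append((tid, len(pts), path_um, path_um / hours))
        rows.extend((tid, f, y, x) for f, y, x in pts)

    if not vel_rows:
        warnings.warn("no track of sufficient length found")
    tracks_df = pd.DataFrame(rows, columns=["track_id", "frame", "y", "x"])
    vel_df = pd.DataFrame(
        vel_rows, columns=["track_id", "n_frames", "path_um", "velocity_um_per_h"]
    )
    return TipTrackSet(tracks=tracks_df, velocities=vel_df,
                       meta={"max_link_um": max_link_um})


@dataclass
class Morphometrics:
    """Per-frame areas and endpoint branch measurements."""

    area_um2: np.ndarray
    fold_change: np.ndarray
    n_branches: int
    base_diameters_um: np.ndarray


def morphometrics(stack: MaskStack, border_px: int = 2) -> Morphometrics:
    """Areas, fold change versus frame 0, branch count and base diameters.

    Branch count is the number of skeleton endpoints of the final frame;
    the base diameter of a branch is twice the distance-transform value at
    the skeleton junction where the branch meets the main body (or at the
    far end of the skeleton path if no junction exists).
    """
    areas = stack.frames.sum(axis=(1, 2)) * stack.pixel_size_um**2
    fold = areas / areas[0] if areas[0] > 0 else np.full_like(areas, np.nan)

    final = stack.frames[-1]
    tips = find_tips(final, border_px=border_px)
    edt = ndi.distance_transform_edt(final)
    diameters = [
        2.0 * edt[base] * stack.pixel_size_um
        for base in (_branch_base(final, tuple(tip), edt) for tip in tips)
    ]
    return Morphometrics(
        area_um2=areas.astype(float),
        fold_change=fold.astype(float),
        n_branches=len(tips),
        base_diameters_um=np.array(diameters, dtype=float),
    )


def _branch_base(
    mask: np.ndarray, tip: tuple[int, int], edt: np.ndarray
) -> tuple[int, int]:
    """Base landmark of the branch starting at ``tip``.

    Walk the skeleton from the tip; the base is the first junction pixel
    (skeleton degree >= 3) where the branch meets the main body, or — when
    the skeleton has no junction (a bare branch) — the widest point (max
    distance-transform) along the walked path.
    """
    skel = skeletonize(mask.astype(bool))
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def neighbors(p):
        out = []
        for dy, dx in offsets:
            q = (p[0] + dy, p[1] + dx)
            if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                out.append(q)
        return out

    prev, cur = None, tip
    path = [tip]
    for _ in range(int(skel.sum())):
        if len(neighbors(cur)) >= 3:
            return cur
        nbrs = [q for q in neighbors(cur) if q != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
        path.append(cur)
    return max(path, key=lambda p: edt[p])


def edu_fraction(
    nuclei_channel: np.ndarray,
    edu_channel: np.ndarray,
    epithelium_mask: np.ndarray,
    min_sigma: float = 3.0,
    max_sigma: float = 8.0,
    detect_threshold: float = 0.05,
    edu_threshold: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Percentage of EdU-positive nuclei inside the epithelium mask.

    Nuclei are LoG blobs on the (normalized) nuclear channel within the
    mask; a nucleus is EdU-positive when its mean EdU intensity in a disk
    of its detected radius exceeds ``edu_threshold`` (default: Otsu over
    all nuclear means). Returns the percentage and the per-nucleus table.
    """
    mask = epithelium_mask.astype(bool)
    if nuclei_channel.shape != mask.shape or edu_channel.shape != mask.shape:
        raise ValueError("channels and mask must share shape")
    chan = nuclei_channel.astype(float)
    if chan.max() > chan.min():
        chan = (chan - chan.min()) / (chan.max() - chan.min())
    blobs = blob_log(
        chan, min_sigma=min_sigma, max_sigma=max_sigma, num_sigma=6,
        threshold=detect_threshold,
    )
    blobs = [
        (y, x, s) for y, x, s in blobs
        if 0 <= int(y) < mask.shape[0] and 0 <= int(x) < mask.shape[1]
        and mask[int(y), int(x)]
    ]
    if not blobs:
        raise ValueError("no nuclei detected inside the mask")

    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    edu = edu_channel.astype(float)
    rows = []
    for y, x, s in blobs:
        region = (yy - y) ** 2 + (xx - x) ** 2 <= s**2
        rows.append((y, x, s, float(edu[region].mean())))
    table = pd.DataFrame(rows, columns=["y", "x", "sigma", "edu_mean"])

    means = table["edu_mean"].to_numpy()
    if edu_threshold is None:
        if np.ptp(means) == 0:
            positive = means > 0  # all-dark -> none, all-bright -> all
        else:
            positive = means > threshold_otsu(means)
    else:
        positive = means > edu_threshold
    table["edu_positive"] = positive
    pct = 100.0 * positive.sum() / len(table)
    return pct, table
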