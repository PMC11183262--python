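"""smFISH quantification: segmentation, spot detection, ratios, rings."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from mammodev.fish import (
    BudImage,
    detect_spots,
    per_cell_counts_and_ratio,
    ring_map,
    ring_stats,
    segment_bud_cells,
)
from mammodev.simulate import BudImageSpec, gen_bud_image


def _bud_image(channels, truth):
    return BudImage(channels=channels, bud_mask=truth.bud_mask)


class TestSegmentBudCells:
    def test_recovers_voronoi_cells(self):
        spec = BudImageSpec(
            image_shape=(256, 256), n_cells=20, noise_sd=0.02,
            ring_density_profile={("A", 1): 0.0}, seed=8,
        )
        channels, truth = gen_bud_image(spec)
        labelmap = segment_bud_cells(_bud_image(channels, truth))
        matched = 0
        for lab in range(1, spec.n_cells + 1):
            region = truth.cell_labels == lab
            found = labelmap.labels[region]
            found = found[found > 0]
            if found.size == 0:
                continue
            best = np.bincount(found).argmax()
            inter = (region & (labelmap.labels == best)).sum()
            union = (region | (labelmap.labels == best)).sum()
            if inter / union > 0.5:
                matched += 1
        assert matched >= 0.9 * spec.n_cells

    def test_uniform_membrane_gives_single_region(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[8:56, 8:56] = True
        img = BudImage(channels={"membrane": np.ones((64, 64))}, bud_mask=mask)
        labelmap = segment_bud_cells(img)
        assert labelmap.labels[mask].min() == 1
        assert labelmap.labels.max() == 1

    def test_no_labels_outside_mask_and_mask_partitioned(self, bud):
        _, channels, truth = bud
        labelmap = segment_bud_cells(_bud_image(channels, truth))
        assert (labelmap.labels[~truth.bud_mask] == 0).all()
        assert (labelmap.labels[truth.bud_mask] > 0).all()

    def test_empty_mask_rejected(self):
        img = BudImage(
            channels={"membrane": np.ones((32, 32))},
            bud_mask=np.zeros((32, 32), dtype=bool),
        )
        with pytest.raises(ValueError, match="empty"):
            segment_bud_cells(img)


def _render_spots(coords, shape=(128, 128), sigma=1.5, amplitude=1.0,
                  noise_sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for y, x in coords:
        img += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
        )
    return img + rng.normal(0, noise_sd, shape)


class TestDetectSpots:
    def test_blank_noise_channel_yields_no_spots(self):
        rng = np.random.default_rng(0)
        chan = rng.normal(0, 0.01, (128, 128))
        assert len(detect_spots(chan, "A", threshold=0.1)) == 0

    def test_high_snr_spots_recovered(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(15, 113, size=(50, 2))
        # enforce spacing so ground-truth spots are resolvable
        keep = []
        for c in coords:
            if all(np.linalg.norm(c - coords[k]) > 8 for k in keep):
                keep.append(np.where((coords == c).all(1))[0][0])
        coords = coords[keep]
        img = _render_spots(coords, sigma=1.5, amplitude=1.0, noise_sd=0.1)
        spots = detect_spots(img, "A")
        found = spots[["y", "x"]].to_numpy(dtype=float)
        d, _ = cKDTree(found).query(coords)
        recall = (d <= 2.0).mean()
        d2, _ = cKDTree(coords).query(found)
        precision = (d2 <= 2.0).mean()
        assert recall >= 0.95 and precision >= 0.95

    def test_scale_selection_close_to_true_sigma(self):
        for sigma in (1.2, 1.6):
            img = _render_spots([(64.0, 64.0)], sigma=sigma, noise_sd=0.0)
            spots = detect_spots(img, "A", threshold=0.05)
            assert len(spots) == 1
            step = (2.0 - 1.0) / 4  # 5 scales in [1, 2]
            assert abs(spots["sigma"].iloc[0] - sigma) <= step + 1e-9

    def test_translation_equivariance(self):
        coords = [(40.0, 50.0), (70.0, 30.0), (90.0, 90.0)]
        img = _render_spots(coords, noise_sd=0.02, seed=2)
        s0 = detect_spots(img, "A", threshold=0.1)
        dy, dx = 7, -5
        s1 = detect_spots(np.roll(img, (dy, dx), axis=(0, 1)), "A", threshold=0.1)
        p0 = np.sort(s0[["y", "x"]].to_numpy() + [dy, dx], axis=0)
        p1 = np.sort(s1[["y", "x"]].to_numpy(), axis=0)
        np.testing.assert_array_equal(p0, p1)

    def test_constant_channel_yields_no_spots(self):
        assert len(detect_spots(np.full((64, 64), 3.0), "A")) == 0


class TestPerCellCountsAndRatio:
    def _labelmap(self):
        from mammodev.fish import CellLabelMap

        labels = np.zeros((20, 20), dtype=int)
        labels[2:10, 2:10] = 1
        labels[12:18, 12:18] = 2
        cells = pd.DataFrame(
            {"label": [1, 2], "centroid_y": [5.5, 14.5],
             "centroid_x": [5.5, 14.5], "area_px": [64, 36]}
        )
        return CellLabelMap(labels=labels, cells=cells)

    def _spots(self, rows):
        return pd.DataFrame(rows, columns=["probe", "y", "x"])

    def test_pure_a_cell_ratio_one_and_mixed_half(self):
        spots = self._spots(
            [("A", 3, 3), ("A", 4, 5), ("A", 5, 4),
             ("A", 13, 13), ("A", 14, 14), ("B", 15, 15), ("B", 16, 16)]
        )
        table, rgb = per_cell_counts_and_ratio(spots, self._labelmap(), "A", "B")
        assert table.set_index("label").loc[1, "ratio"] == 1.0
        assert table.set_index("label").loc[2, "ratio"] == 0.5
        assert rgb.shape == (20, 20, 3)

    def test_cell_without_spots_gets_nan_and_gray(self):
        spots = self._spots([("A", 3, 3), ("B", 3, 4)])
        table, rgb = per_cell_counts_and_ratio(spots, self._labelmap(), "A", "B")
        assert np.isnan(table.set_index("label").loc[2, "ratio"])
        np.testing.assert_allclose(rgb[14, 14], [0.5, 0.5, 0.5])

    def test_count_conservation(self, bud):
        _, channels, truth = bud
        from mammodev.fish import CellLabelMap

        labels = truth.cell_labels
        cells = pd.DataFrame(
            {
                "label": np.unique(labels[labels > 0]),
                "centroid_y": 0.0, "centroid_x": 0.0, "area_px": 0,
            }
        )
        labelmap = CellLabelMap(labels=labels, cells=cells)
        table, _ = per_cell_counts_and_ratio(
            truth.spots, labelmap, "Anxa1", "Cxcl14"
        )
        inside = truth.spots[
            labels[truth.spots["y"], truth.spots["x"]] > 0
        ]
        assert table["nA"].sum() == (inside["probe"] == "Anxa1").sum()
        assert table["nB"].sum() == (inside["probe"] == "Cxcl14").sum()

    def test_unknown_probe_rejected(self):
        spots = self._spots([("A", 3, 3)])
        with pytest.raises(ValueError, match="unknown probe"):
            per_cell_counts_and_ratio(spots, self._labelmap(), "A", "Z")


class TestRings:
    def test_rings_partition_mask_exactly(self, bud):
        _, _, truth = bud
        rings = ring_map(truth.bud_mask)
        assert (rings[~truth.bud_mask] == 0).all()
        assert set(np.unique(rings[truth.bud_mask])) == {1, 2, 3}
        # disjoint bands whose union is the mask, as a pixel-set identity
        assert ((rings > 0) == truth.bud_mask).all()

    def test_all_spots_at_center_are_inner(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[8:56, 8:56] = True
        spots = pd.DataFrame({"probe": ["A"] * 5, "y": [31] * 5, "x": [31] * 5})
        stats = ring_stats([spots], [mask])
        inner = stats.counts.query("ring == 1")
        assert inner["percentage"].iloc[0] == 100.0

    def test_percentages_sum_to_100_per_probe(self, bud):
        _, _, truth = bud
        stats = ring_stats([truth.spots], [truth.bud_mask])
        sums = stats.counts.groupby(["replicate", "probe"])["percentage"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_uniform_spots_match_ring_areas(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((128, 128), dtype=bool)
        yy, xx = np.mgrid[0:128, 0:128]
        mask[(yy - 63.5) ** 2 + (xx - 63.5) ** 2 <= 55**2] = True
        pts = np.argwhere(mask)
        chosen = pts[rng.choice(len(pts), size=3000)]
        spots = pd.DataFrame(
            {"probe": "A", "y": chosen[:, 0], "x": chosen[:, 1]}
        )
        stats = ring_stats([spots], [mask])
        rings = ring_map(mask)
        for ring in (1, 2, 3):
            p_area = (rings == ring).sum() / mask.sum()
            p_obs = stats.counts.query("ring == @ring")["percentage"].iloc[0] / 100
            se = np.sqrt(p_area * (1 - p_area) / 3000)
            assert abs(p_obs - p_area) < 4 * se

    def test_biased_probes_give_significant_interaction(self):
        """Five replicate buds with opposed radial profiles: the probe-by-
        ring interaction must be strongly significant."""
        tables, masks = [], []
        for rep in range(5):
            spec = BudImageSpec(image_shape=(256, 256), n_cells=60, seed=20 + rep)
            _, truth = gen_bud_image(spec)
            tables.append(truth.spots)
            masks.append(truth.bud_mask)
        stats = ring_stats(tables, masks)
        assert stats.anova.loc["probe:ring", "PR(>F)"] < 0.01
        assert not stats.contrasts.empty

    def test_empty_replicate_excluded_with_warning(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:28, 4:28] = True
        good = pd.DataFrame({"probe": ["A"] * 3, "y": [15] * 3, "x": [15] * 3})
        empty = pd.DataFrame({"probe": [], "y": [], "x": []})
        with pytest.warns(UserWarning, match="excluded"):
            stats = ring_stats([good, empty], [mask, mask])
        assert set(stats.counts["replicate"]) == {0}
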