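"""Cluster masks, colocalization statistics, related ions, report bundle."""

import numpy as np
import pandas as pd
import pytest

from msipipe import Datacube, MzAxis, synthgen
from msipipe.interpretation import (
    RelatedIonTable,
    annotate_related_ions,
    build_report,
    cluster_mask,
    colocalization,
)
from msipipe.peaks import dataset_peaks
from msipipe.unsupervised import (
    SegmentationMap,
    kmeans_segment,
    peak_features,
    spatially_aware_segment,
)


def _segmap(labels_grid):
    grid = np.asarray(labels_grid)
    rr, cc = np.nonzero(grid > 0)
    coords = np.column_stack([cc + 1, rr + 1])
    labels = grid[rr, cc]
    return SegmentationMap(labels=labels, k=int(labels.max()), coords=coords,
                           grid_shape=grid.shape)


def _mask_cube(mask_vec, n_extra_channels=0, seed=0):
    """Cube whose first channel equals the mask, second its complement."""
    rng = np.random.default_rng(seed)
    n = mask_vec.size
    channels = [mask_vec.astype(float), 1.0 - mask_vec]
    channels += [rng.random(n) for _ in range(n_extra_channels)]
    inten = np.column_stack(channels)
    axis = MzAxis(np.arange(500.0, 500.0 + inten.shape[1] * 1.0))
    side = int(np.sqrt(n))
    rows = -(-n // side)
    coords = np.array([(x, y) for y in range(1, rows + 1)
                       for x in range(1, side + 1)][:n])
    return Datacube(coords, inten, axis)


class TestClusterMask:
    def test_single_cluster_mask_all_ones(self):
        seg = _segmap(np.ones((4, 4), dtype=int))
        mask = cluster_mask(seg, 1)
        assert np.all(mask.measured_values == 1.0)

    def test_two_cluster_masks_partition_measured_pixels(self):
        grid = np.ones((4, 6), dtype=int)
        grid[:, 3:] = 2
        seg = _segmap(grid)
        m1 = cluster_mask(seg, 1).measured_values
        m2 = cluster_mask(seg, 2).measured_values
        np.testing.assert_array_equal(m1 + m2, 1.0)

    def test_mask_count_equals_cluster_size(self):
        grid = np.ones((5, 5), dtype=int)
        grid[:2, :2] = 2
        seg = _segmap(grid)
        assert cluster_mask(seg, 2).measured_values.sum() == 4

    def test_unknown_cluster_rejected(self):
        seg = _segmap(np.ones((3, 3), dtype=int))
        with pytest.raises(KeyError):
            cluster_mask(seg, 5)


class TestColocalization:
    MASK = np.array([1.0] * 32 + [0.0] * 32)

    def test_channel_identical_to_mask_r_one(self):
        cube = _mask_cube(self.MASK)
        recs = colocalization(cube, self.MASK)
        best = recs[0]
        assert best.r == pytest.approx(1.0)
        assert best.selected

    def test_complement_channel_r_minus_one_not_selected(self):
        cube = _mask_cube(self.MASK)
        recs = {r.mz: r for r in colocalization(cube, self.MASK)}
        anti = recs[501.0]
        assert anti.r == pytest.approx(-1.0)
        assert not anti.selected

    def test_independent_noise_channels_rarely_selected(self):
        # null-distribution oracle: ~alpha of unit-variance noise channels
        mask = np.array([1.0] * 500 + [0.0] * 500)
        cube = _mask_cube(mask, n_extra_channels=100, seed=1)
        recs = {r.mz: r for r in colocalization(cube, mask)}
        noise = [recs[500.0 + 2 + j] for j in range(100)]
        small_r = sum(abs(r.r) < 0.1 for r in noise)
        unselected = sum(not r.selected for r in noise)
        assert small_r >= 95
        assert unselected >= 95

    def test_constant_channel_flagged_not_nan(self):
        mask = self.MASK
        cube = _mask_cube(mask)
        inten = cube.intensities.copy()
        inten[:, 1] = 2.5
        cube = Datacube(cube.coords, inten, cube.axis)
        recs = {r.mz: r for r in colocalization(cube, mask)}
        rec = recs[501.0]
        assert rec.degenerate and not rec.selected
        assert np.isfinite(rec.r) and np.isfinite(rec.p)

    def test_invariant_to_positive_channel_rescaling(self):
        cube = _mask_cube(self.MASK, n_extra_channels=3, seed=2)
        scaled = cube.copy_with(intensities=cube.intensities * np.array([1, 5, 0.3, 17, 2.0]))
        a = colocalization(cube, self.MASK)
        b = colocalization(scaled, self.MASK)
        for ra, rb in zip(a, b):
            assert ra.r == pytest.approx(rb.r, abs=1e-12)
            assert ra.selected == rb.selected

    def test_selection_monotone_in_alpha(self):
        cube = _mask_cube(self.MASK, n_extra_channels=20, seed=3)
        tight = {r.mz for r in colocalization(cube, self.MASK, alpha=0.001)
                 if r.selected}
        loose = {r.mz for r in colocalization(cube, self.MASK, alpha=0.05)
                 if r.selected}
        assert tight <= loose

    def test_degenerate_mask_rejected(self):
        cube = _mask_cube(self.MASK)
        with pytest.raises(ValueError):
            colocalization(cube, np.ones_like(self.MASK))

    def test_ground_truth_region_peaks_recovered(self, noisy_two_region):
        """Region-specific peaks reach r >= 0.8 in their own cluster's list
        and no everywhere-peak is selected (specificity)."""
        cube, truth = noisy_two_region
        F = peak_features(cube, dataset_peaks(cube))
        seg = spatially_aware_segment(F, cube, 2, radius=2, seed=1)
        overlap_left = np.mean(
            (seg.labels == 1) == (truth.region_labels == 1))
        left_cluster = 1 if overlap_left > 0.5 else 2
        by_region_cluster = {"left": left_cluster, "right": 3 - left_cluster}
        axis = cube.axis
        for region, cluster in by_region_cluster.items():
            other = "right" if region == "left" else "left"
            other_mzs = {p.mz for p in truth.peaks[other]}
            specific = [p for p in truth.peaks[region] if p.mz not in other_mzs]
            assert specific
            recs = {r.mz: r for r in colocalization(cube, cluster_mask(seg, cluster))}
            for peak in specific:
                rec = recs[float(axis.values[axis.nearest_channel(peak.mz)])]
                assert rec.r >= 0.8, (region, peak.mz, rec.r)
                assert rec.selected
            for peak in truth.peaks["everywhere"]:
                rec = recs[float(axis.values[axis.nearest_channel(peak.mz)])]
                assert not rec.selected, (cluster, peak.mz, rec.r)


class TestRelatedIons:
    def test_delta_17_is_ammonia_loss(self):
        hits = annotate_related_ions(np.array([800.4, 817.4]))
        assert hits == [(800.4, 817.4, "ammonia loss")]

    def test_delta_18_is_water_loss(self):
        hits = annotate_related_ions(np.array([800.4, 818.4]))
        assert hits == [(800.4, 818.4, "water loss")]

    def test_delta_16_oxidation_and_delta_1_isotope(self):
        hits = annotate_related_ions(np.array([800.0, 801.0, 816.0]))
        relations = {(a, b): rel for a, b, rel in hits}
        assert relations[(800.0, 801.0)] == "isotope"
        assert relations[(800.0, 816.0)] == "oxidation"

    def test_unrelated_pair_empty(self):
        assert annotate_related_ions(np.array([800.4, 900.0])) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            annotate_related_ions(np.array([900.0, 800.0]))

    def test_custom_tolerance(self):
        table = RelatedIonTable(tol=0.05)
        assert annotate_related_ions(np.array([800.0, 817.1]), table) == []


class TestReport:
    def test_two_cluster_report_two_pages_and_consistent_csv(self, tmp_path,
                                                             clean_two_region):
        cube, _ = clean_two_region
        F = peak_features(cube, dataset_peaks(cube))
        seg = kmeans_segment(F, cube, 2, seed=0)
        pages = build_report(seg, cube, tmp_path)
        assert sorted(pages) == [1, 2]
        for cid in (1, 2):
            assert (tmp_path / f"cluster_{cid}.png").exists()
            table = pd.read_csv(tmp_path / f"cluster_{cid}.csv")
            assert {"mz", "r", "p", "q", "selected", "q90_intensity"} <= set(table.columns)
            recs = colocalization(cube, cluster_mask(seg, cid))
            # CSV mirrors the computed records to 6 significant digits
            assert table.loc[0, "mz"] == pytest.approx(recs[0].mz, rel=1e-5)
            assert table.loc[0, "r"] == pytest.approx(recs[0].r, rel=1e-4)

    def test_cluster_without_significant_ions_still_gets_page(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 64
        inten = rng.random((n, 6)) + 0.5
        axis = MzAxis(np.arange(500.0, 506.0))
        coords = np.array([(x, y) for y in range(1, 9) for x in range(1, 9)])
        cube = Datacube(coords, inten, axis)
        grid = np.ones((8, 8), dtype=int)
        grid[:, 4:] = 2
        seg = _segmap(grid)
        pages = build_report(seg, cube, tmp_path, alpha=1e-12)
        assert sorted(pages) == [1, 2]
        assert (tmp_path / "cluster_1.png").exists()
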