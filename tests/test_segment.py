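"""Segmentation-stage tests: islet mask, nuclei, label painting, propagation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from oracles import propagation_oracle

from isletquant.imops import gaussian_blur
from isletquant.segment import (
    IsletParams,
    NucleiParams,
    NucleusSet,
    PropagationParams,
    _disk_iou,
    _growth_region,
    detect_nuclei,
    make_guide,
    mask_channel,
    paint_labels,
    propagate_cells,
    segment_islet,
)
from isletquant.synthgen import generate_truth, render_image, render_probability_map


def _gaussian_blob(shape, center, sigma, amplitude=1.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


class TestSegmentIslet:
    def test_uniform_bright_map_full_mask(self):
        pm = np.full((64, 64), 255, dtype=np.uint8)
        assert segment_islet(pm).all()

    def test_uniform_zero_map_empty_mask_with_warning(self):
        pm = np.zeros((64, 64), dtype=np.uint8)
        with pytest.warns(UserWarning):
            mask = segment_islet(pm)
        assert not mask.any()

    def test_synthetic_disk_recovered_with_high_jaccard(self):
        # the sigma-20 blur inside the pipeline moves the recovered boundary
        # by a few pixels; at a realistically large islet the overlap is high
        from isletquant.synthgen import GeometryParams

        params = GeometryParams(field_shape=(1024, 1024), islet_radius_px=400.0, n_cells=10)
        truth = generate_truth(params, seed=30)
        pm = render_probability_map(truth, blur_sigma_px=5, noise_sd=8, seed=31)
        mask = segment_islet(pm)
        inter = np.count_nonzero(mask & truth.islet_mask)
        union = np.count_nonzero(mask | truth.islet_mask)
        assert inter / union >= 0.95

    def test_invariant_to_subthreshold_background_offset(self, small_geometry):
        """Adding a constant <= offset to a zero-background map leaves the mask unchanged."""
        truth = generate_truth(small_geometry, seed=32)
        pm = render_probability_map(truth, blur_sigma_px=0, noise_sd=0, seed=0)
        shifted = np.clip(pm.astype(int) + 30, 0, 255).astype(np.uint8)
        assert np.array_equal(segment_islet(pm), segment_islet(shifted))

    def test_rejects_non_8bit(self):
        with pytest.raises(ValueError):
            segment_islet(np.zeros((8, 8), dtype=float))


class TestMaskChannel:
    def test_full_and_empty_masks(self):
        img = np.random.default_rng(0).random((10, 10))
        assert np.array_equal(mask_channel(img, np.ones((10, 10), bool)), img)
        assert (mask_channel(img, np.zeros((10, 10), bool)) == 0).all()

    def test_half_frame(self):
        img = np.ones((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        out = mask_channel(img, mask)
        assert out[:5].all() and not out[5:].any()


class TestDetectNuclei:
    def test_single_blob_one_detection(self):
        img = _gaussian_blob((100, 100), (50, 50), sigma=6)
        det = detect_nuclei(img)
        assert len(det) == 1
        assert np.hypot(*(det.centroids[0] - (50, 50))) <= 1.0

    def test_two_distant_blobs(self):
        img = _gaussian_blob((120, 200), (60, 60), 6) + _gaussian_blob((120, 200), (60, 140), 6)
        det = detect_nuclei(img)
        assert len(det) == 2

    def test_all_zero_image_empty_set(self):
        assert len(detect_nuclei(np.zeros((50, 50)))) == 0

    def test_high_overlap_suppressed_keeps_higher_score(self):
        # two near-coincident equal blobs: fitted disks overlap far above 0.8 IoU
        img = _gaussian_blob((80, 80), (40, 38), 6) + _gaussian_blob((80, 80), (40, 42), 6)
        det = detect_nuclei(img, NucleiParams(blur_sigma_px=3))
        assert len(det) == 1
        # the survivor is the best-scoring (tie -> smaller (row, col)) candidate
        assert det.scores[0] == det.scores.max()

    def test_disk_iou_matches_rasterization(self):
        # oracle: direct pixel rasterization of the two disks
        rng = np.random.default_rng(33)
        for _ in range(10):
            c1 = rng.uniform(30, 50, 2)
            c2 = c1 + rng.uniform(-15, 15, 2)
            r1, r2 = rng.uniform(5, 15, 2)
            rr, cc = np.mgrid[0:400, 0:400] * 0.25  # quarter-pixel grid for accuracy
            d1 = (rr - c1[0]) ** 2 + (cc - c1[1]) ** 2 <= r1**2
            d2 = (rr - c2[0]) ** 2 + (cc - c2[1]) ** 2 <= r2**2
            raster = np.count_nonzero(d1 & d2) / np.count_nonzero(d1 | d2)
            assert _disk_iou(c1, r1, c2, r2) == pytest.approx(raster, abs=0.02)


class TestPaintLabels:
    def test_empty_set_blank_image(self):
        empty = NucleusSet(np.empty((0, 2)), np.empty(0), np.empty(0), (20, 20))
        assert (paint_labels(empty) == 0).all()

    def test_disjoint_disks_full_areas(self):
        nuclei = NucleusSet(np.array([[10.0, 10.0], [10.0, 40.0]]),
                            np.array([4.0, 4.0]), np.array([1.0, 0.9]), (20, 50))
        labels = paint_labels(nuclei)
        rr, cc = np.mgrid[0:20, 0:50]
        for lab, (r, c) in ((1, (10, 10)), (2, (10, 40))):
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= 16.0
            assert (labels == lab).sum() == disk.sum()

    def test_overlapping_disks_stay_disjoint(self):
        nuclei = NucleusSet(np.array([[15.0, 15.0], [15.0, 20.0]]),
                            np.array([5.0, 5.0]), np.array([0.8, 1.0]), (31, 41))
        labels = paint_labels(nuclei)
        rr, cc = np.mgrid[0:31, 0:41]
        d1 = (rr - 15) ** 2 + (cc - 20) ** 2 <= 25  # higher score painted first
        d2 = (rr - 15) ** 2 + (cc - 15) ** 2 <= 25
        assert np.array_equal(labels > 0, d1 | d2)
        assert np.array_equal(labels == 1, d1)  # label 1 = first painted, never overwritten
        assert ((labels == 2) == (d2 & ~d1)).all()


class TestMakeGuide:
    def test_identical_channels_guide_is_rescaled_channel(self):
        plane = np.linspace(0.2, 0.8, 64).reshape(8, 8)
        guide = make_guide({"insulin": plane, "glucagon": plane, "igfbp7": plane})
        assert guide.min() == 0.0 and guide.max() == 1.0

    def test_constant_zero_channel_ignored(self):
        rng = np.random.default_rng(1)
        a = rng.random((8, 8))
        with pytest.warns(UserWarning):
            guide = make_guide({"insulin": a, "glucagon": np.zeros((8, 8)), "igfbp7": a})
        expected = (a - a.min()) / (a.max() - a.min())
        assert np.allclose(guide, expected)

    def test_all_constant_channels_zero_guide(self):
        with pytest.warns(UserWarning):
            guide = make_guide({"insulin": np.full((4, 4), 0.2),
                                "glucagon": np.full((4, 4), 0.5),
                                "igfbp7": np.full((4, 4), 0.9)})
        assert (guide == 0).all()


class TestPropagateCells:
    def test_uniform_guide_single_seed_fills_frame(self):
        seeds = np.zeros((15, 15), dtype=np.int32)
        seeds[7, 7] = 1
        out = propagate_cells(seeds, np.full((15, 15), 0.5))
        assert (out == 1).all()

    def test_uniform_guide_two_seeds_tie_to_smaller_label(self):
        seeds = np.zeros((9, 21), dtype=np.int32)
        seeds[4, 5] = 1
        seeds[4, 15] = 2
        out = propagate_cells(seeds, np.full((9, 21), 0.5))
        # strictly closer pixels get their seed; the equidistant column gets label 1
        assert (out[:, :10] == 1).all()
        assert (out[:, 11:] == 2).all()
        assert (out[:, 10] == 1).all()

    def test_no_seeds_rejected(self):
        with pytest.raises(ValueError):
            propagate_cells(np.zeros((5, 5), dtype=np.int32), np.zeros((5, 5)))

    def test_seeds_never_reassigned(self):
        rng = np.random.default_rng(40)
        guide = rng.random((20, 20))
        seeds = np.zeros((20, 20), dtype=np.int32)
        seeds[2:5, 2:5] = 3
        seeds[15:18, 15:18] = 1
        out = propagate_cells(seeds, guide)
        assert np.array_equal(out[seeds > 0], seeds[seeds > 0])

    def test_labeled_pixels_connected_to_their_seed(self):
        from scipy import ndimage

        rng = np.random.default_rng(41)
        guide = rng.random((25, 25))
        seeds = np.zeros((25, 25), dtype=np.int32)
        seeds[3, 3] = 1
        seeds[20, 20] = 2
        seeds[3, 20] = 3
        out = propagate_cells(seeds, guide)
        for lab in (1, 2, 3):
            region = out == lab
            comp, n = ndimage.label(region, structure=np.ones((3, 3)))
            seed_comp = set(np.unique(comp[(seeds == lab) & region]))
            assert set(np.unique(comp[region])) <= seed_comp

    def test_ridge_fixture_matches_dijkstra_oracle(self):
        guide = np.full((15, 15), 0.1)
        guide[:, 7] = 0.9  # bright vertical ridge between the seeds
        seeds = np.zeros((15, 15), dtype=np.int32)
        seeds[7, 2] = 1
        seeds[7, 12] = 2
        params = PropagationParams(regularization_lambda=0.25, smoothing_sigma_px=0.0)
        out = propagate_cells(seeds, guide, params)
        smoothed = gaussian_blur(guide, params.smoothing_sigma_px)
        growth = _growth_region(smoothed, params.threshold_correction) | (seeds > 0)
        expected = propagation_oracle(seeds, smoothed, growth, 0.25)
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("lam", [0.0, 0.25, 5.0])
    def test_random_instances_match_oracle(self, lam):
        rng = np.random.default_rng(42)
        for _ in range(10):
            shape = (int(rng.integers(6, 20)), int(rng.integers(6, 20)))
            guide = rng.random(shape)
            seeds = np.zeros(shape, dtype=np.int32)
            n_seeds = int(rng.integers(1, 4))
            pos = rng.choice(shape[0] * shape[1], size=n_seeds, replace=False)
            seeds.flat[pos] = np.arange(1, n_seeds + 1)
            params = PropagationParams(regularization_lambda=lam, smoothing_sigma_px=1.0)
            out = propagate_cells(seeds, guide, params)
            smoothed = gaussian_blur(guide, 1.0)
            growth = _growth_region(smoothed, 1.0) | (seeds > 0)
            expected = propagation_oracle(seeds, smoothed, growth, lam)
            assert np.array_equal(out, expected)

    def test_lambda_monotonically_confines_barrier_crossing(self):
        """More spatial regularisation never sends more pixels across a ridge."""
        guide = np.full((21, 21), 0.2)
        guide[:, 10] = 0.95
        seeds = np.zeros((21, 21), dtype=np.int32)
        seeds[10, 3] = 1
        seeds[10, 17] = 2
        crossings = []
        for lam in (0.0, 0.1, 0.25, 1.0, 5.0):
            out = propagate_cells(seeds, guide,
                                  PropagationParams(regularization_lambda=lam,
                                                    smoothing_sigma_px=0.0))
            crossings.append(int((out[:, :10] == 2).sum() + (out[:, 11:] == 1).sum()))
        assert all(a >= b for a, b in zip(crossings, crossings[1:]))


def test_nuclei_recovery_on_noiseless_fields(small_geometry, noiseless_model):
    """Detection + painting recovers >=99% of true nuclei with no false positives."""
    found = total = fp = 0
    for seed in range(3):
        truth = generate_truth(small_geometry, seed=50 + seed, model=noiseless_model)
        img = render_image(truth, noiseless_model, seed=60 + seed)
        pm = render_probability_map(truth, 5, 0, seed=0)
        det = detect_nuclei(mask_channel(img["nuclear"], segment_islet(pm)))
        d, _ = cKDTree(det.centroids).query(truth.nucleus_centroids)
        found += int((d <= truth.nucleus_radii).sum())
        total += len(truth.nucleus_centroids)
        d2, _ = cKDTree(truth.nucleus_centroids).query(det.centroids)
        fp += int((d2 > truth.nucleus_radii.max()).sum())
        labels = paint_labels(det)
        assert labels.max() == len(det)
    assert found / total >= 0.99 and fp == 0
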