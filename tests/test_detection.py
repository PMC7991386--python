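import numpy as np
import pytest

from drgcal import (
    DetectionParams,
    ImageStack,
    LabelMap,
    VarianceMap,
    detect_neurons,
    dual_threshold,
    morph_close_open,
    remove_small_and_border,
    select_by_size,
    variance_map,
    watershed_labels,
)
from oracles import close_open_bruteforce, local_mean_bruteforce, variance_bruteforce


def _disc(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestVarianceMap:
    def test_constant_stack_is_zero(self):
        stack = ImageStack(np.full((6, 5, 5), 42, dtype=np.uint8))
        v = variance_map(stack)
        assert np.all(v.values == 0)
        assert v.source_frames == 6

    def test_alternating_pixel_closed_form(self):
        frames = np.zeros((4, 3, 3))
        frames[::2, 1, 1] = 0
        frames[1::2, 1, 1] = 2
        v = variance_map(ImageStack(frames))
        assert v.values[1, 1] == pytest.approx(1.0)
        assert v.values[0, 0] == 0

    def test_matches_bruteforce_oracle(self, rng):
        frames = rng.uniform(0, 255, size=(10, 5, 5))
        v = variance_map(ImageStack(frames), chunk=3)  # chunking must not matter
        np.testing.assert_allclose(v.values, variance_bruteforce(frames), atol=1e-10)


class TestDualThreshold:
    def test_uniform_map_all_false_on_ties(self):
        v = np.full((10, 10), 5.0)
        mask = dual_threshold(v, h_global=1.0, neighborhood=3, offset=0.0)
        assert not mask.any()  # strict > against local mean fails everywhere

    def test_single_bright_pixel(self):
        v = np.zeros((9, 9))
        v[4, 4] = 10.0
        mask = dual_threshold(v, h_global=5.0, neighborhood=3)
        assert mask[4, 4] and mask.sum() == 1

    def test_matches_bruteforce_local_mean(self, rng):
        v = rng.uniform(0, 100, size=(16, 16))
        h = 30.0
        got = dual_threshold(v, h, neighborhood=5, offset=2.0)
        lm = local_mean_bruteforce(v, 5)
        expected = (v > h) & (v > lm + 2.0)
        np.testing.assert_array_equal(got, expected)

    def test_global_gate_monotone_in_threshold(self, rng):
        v = rng.uniform(0, 100, size=(20, 20))
        hi = dual_threshold(v, 60.0, neighborhood=5)
        lo = dual_threshold(v, 20.0, neighborhood=5)
        assert np.all(lo | ~hi)  # every pixel passing at 60 also passes at 20

    def test_even_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            dual_threshold(np.zeros((4, 4)), 1.0, neighborhood=4)


class TestMorphology:
    def test_solid_square_keeps_interior_loses_corners(self):
        # opening with the cross shaves exactly the four corner pixels of a
        # solid square (no translate of the cross covers a corner)
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        expected = mask.copy()
        for r, c in ((2, 2), (2, 6), (6, 2), (6, 6)):
            expected[r, c] = False
        np.testing.assert_array_equal(morph_close_open(mask), expected)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert not morph_close_open(mask).any()

    def test_matches_minkowski_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((20, 20)) < 0.4
            np.testing.assert_array_equal(morph_close_open(mask), close_open_bruteforce(mask))


class TestCleanup:
    def test_small_feature_threshold_is_strict(self):
        mask = np.zeros((40, 80), dtype=bool)
        mask[5:10, 5:13] = True  # 40 px: kept (only < 40 removed)
        mask[20:25, 20:28] = True
        mask[20, 20] = False  # 39 px: removed
        out = remove_small_and_border(mask, 40)
        assert out[7, 7]
        assert not out[22, 24]

    def test_border_touching_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:10, 5:15] = True  # 100 px touching top edge
        assert not remove_small_and_border(mask, 40).any()

    def test_empty_mask_passthrough(self):
        mask = np.zeros((5, 5), dtype=bool)
        assert not remove_small_and_border(mask, 40).any()


class TestWatershed:
    def test_disjoint_blobs_keep_their_pixels(self):
        mask = _disc((60, 60), (15, 15), 8) | _disc((60, 60), (45, 45), 8)
        lm = watershed_labels(mask)
        assert lm.n_labels == 2
        assert (lm.labels > 0).sum() == mask.sum()

    def test_single_disc_single_label(self):
        lm = watershed_labels(_disc((40, 40), (20, 20), 10))
        assert lm.n_labels == 1

    def test_touching_discs_split_near_bisector(self):
        # centers 30 px apart, radius 18: overlap splits along the midline band
        mask = _disc((80, 100), (40, 35), 18) | _disc((80, 100), (40, 65), 18)
        lm = watershed_labels(mask)
        assert lm.n_labels == 2
        assert lm.labels[40, 35] != lm.labels[40, 65]
        # the boundary column between the two labels lies near col 50
        left = lm.labels[40, 35]
        boundary = max(c for c in range(100) if lm.labels[40, c] == left)
        assert abs(boundary - 50) <= 3

    def test_empty_mask(self):
        lm = watershed_labels(np.zeros((10, 10), dtype=bool))
        assert lm.n_labels == 0


class TestSizeGate:
    @pytest.mark.parametrize(
        "diameter_um,kept", [(25.0, True), (6.0, False), (55.0, False), (10.0, True), (40.0, True)]
    )
    def test_diameter_gate_inclusive(self, diameter_um, kept):
        pixel_size = 0.7
        r_px = diameter_um / 2 / pixel_size
        n = int(np.ceil(2 * r_px)) + 10
        labels = np.zeros((n, n), dtype=np.int32)
        yy, xx = np.mgrid[0:n, 0:n]
        c = n / 2
        disc = (yy - c) ** 2 + (xx - c) ** 2 <= r_px**2
        labels[disc] = 1
        lm = select_by_size(LabelMap(labels, pixel_size), DetectionParams())
        assert (lm.n_labels == 1) == kept


class TestDetectNeurons:
    def test_zero_variance_stack_yields_no_rois(self):
        stack = ImageStack(np.full((5, 64, 64), 100, dtype=np.uint8))
        lm, rois, log = detect_neurons(stack, DetectionParams(expected_neurons=5, max_iterations=3))
        assert rois == []
        assert all(entry["new_rois"] == 0 for entry in log)

    def test_threshold_decays_geometrically(self, small_recording):
        _, stack, _ = small_recording
        params = DetectionParams(expected_neurons=10_000, max_iterations=4, h_global_init=64.0)
        _, _, log = detect_neurons(stack, params)
        for n, entry in enumerate(log):
            assert entry["h_global"] == pytest.approx(64.0 * 0.75**n, rel=0, abs=0)

    def test_determinism(self, small_recording):
        _, stack, _ = small_recording
        params = DetectionParams(expected_neurons=10)
        lm1, _, _ = detect_neurons(stack, params)
        lm2, _, _ = detect_neurons(stack, params)
        np.testing.assert_array_equal(lm1.labels, lm2.labels)

    def test_accepted_rois_disjoint_and_sized(self, detection_result):
        lm, rois, _ = detection_result
        params = DetectionParams()
        for r in rois:
            assert r.area_px >= params.min_feature_px
            assert params.neuron_diameter_min <= r.equivalent_diameter_um <= params.neuron_diameter_max
        # label map is a partition: each positive pixel belongs to one ROI
        areas = np.bincount(lm.labels.ravel())[1:]
        assert sorted(areas.tolist()) == sorted(r.area_px for r in rois)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            DetectionParams(alpha=1.5)
        with pytest.raises(ValueError):
            DetectionParams(neuron_diameter_min=40, neuron_diameter_max=10)
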