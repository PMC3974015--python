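"""ROI statistics and the flanking-ROI attenuation estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cerevasc.errors import (
    EmptyROIError,
    NonPositiveReferenceError,
    OutOfBoundsError,
)
from cerevasc.image import LuminescenceImage
from cerevasc.physics import CameraSpec
from cerevasc.quantify import (
    ROI,
    PolygonROI,
    despike,
    flanking_rois,
    region_reduction,
    roi_mean,
    subtract_background,
    vessel_attenuation,
)
from cerevasc.simulate import (
    COHORT_CAMERA,
    NoiseSpec,
    SceneSpec,
    VesselSpec,
    render_mouse,
    vessel_measurement_roi,
)


def brute_force_roi_mean(arr, roi):
    """Independent oracle: explicit loop over pixel centers."""
    total, count = 0.0, 0
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cx, cy = j + 0.5, i + 0.5
            if roi.x <= cx < roi.x + roi.width and roi.y <= cy < roi.y + roi.height:
                total += arr[i, j]
                count += 1
    return total / count


class TestRoiMean:
    def test_constant_image(self):
        arr = np.full((16, 16), 3.25)
        assert roi_mean(arr, ROI(2, 3, 5, 4)) == pytest.approx(3.25)

    def test_two_by_two_patch(self):
        arr = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert roi_mean(arr, ROI(0, 0, 2, 2)) == pytest.approx(2.5)

    def test_edge_straddle_uses_in_bounds_pixels(self, rng):
        arr = rng.uniform(0, 1, (12, 12))
        roi = ROI(-3, 4, 6, 5)  # sticks out on the left
        assert roi_mean(arr, roi) == pytest.approx(brute_force_roi_mean(arr, roi))

    def test_matches_brute_force_enumeration(self, rng):
        arr = rng.uniform(0, 10, (9, 11))
        for roi in (ROI(1, 2, 4, 3), ROI(0, 0, 11, 9), ROI(5.5, 1.5, 3, 4)):
            assert roi_mean(arr, roi) == pytest.approx(brute_force_roi_mean(arr, roi))

    def test_empty_roi_raises(self):
        arr = np.zeros((8, 8))
        with pytest.raises(EmptyROIError):
            roi_mean(arr, ROI(20, 20, 3, 3))

    def test_polygon_roi_matches_rect(self, rng):
        arr = rng.uniform(0, 1, (10, 10))
        rect = ROI(2, 3, 4, 5)
        poly = PolygonROI(((2, 3), (6, 3), (6, 8), (2, 8)))
        assert roi_mean(arr, poly) == pytest.approx(roi_mean(arr, rect))

    def test_accepts_luminescence_image(self):
        img = LuminescenceImage(np.full((8, 8), 2.0), CameraSpec(8, 8))
        assert roi_mean(img, ROI(0, 0, 8, 8)) == 2.0


class TestBackgroundAndDespike:
    def test_offset_removal_recovers_source(self, rng):
        source = rng.uniform(0, 5, (20, 20))
        source[:5, :5] = 0.0  # source-free corner
        corrupted = source + 7.5
        out = subtract_background(corrupted, ROI(0, 0, 5, 5))
        assert np.allclose(out, source)

    def test_zero_image_stays_zero(self):
        out = subtract_background(np.zeros((6, 6)), ROI(0, 0, 3, 3))
        assert np.allclose(out, 0.0)

    def test_poisson_offset_residual_within_sampling_bound(self, rng):
        lam = 400.0
        arr = rng.poisson(lam, (64, 64)).astype(float)
        bg = ROI(0, 0, 32, 32)
        out = subtract_background(arr, bg)
        n = 32 * 32
        # residual mean of an independent region ~ N(0, 2*lam/n); 4-sigma bound
        other = roi_mean(out, ROI(32, 32, 32, 32))
        assert abs(other) < 4 * math.sqrt(2 * lam / n)

    def test_spike_free_image_unchanged(self, rng):
        arr = rng.uniform(10, 11, (16, 16))
        assert np.allclose(despike(arr), arr)

    def test_single_spike_on_constant_field_replaced(self):
        arr = np.full((15, 15), 5.0)
        arr[7, 7] = 5000.0
        out = despike(arr)
        assert out[7, 7] == 5.0
        assert np.allclose(out, 5.0)

    def test_synthetic_spikes_removed_with_few_false_positives(self, rng):
        lam = 2000.0
        clean = rng.poisson(lam, (128, 128)).astype(float)
        arr = clean.copy()
        spots = [(i, j) for i, j in zip(rng.integers(0, 128, 40),
                                        rng.integers(0, 128, 40))]
        for i, j in spots:
            arr[i, j] += 100 * lam
        out = despike(arr)
        removed = sum(out[i, j] < arr[i, j] for i, j in spots)
        assert removed >= 0.99 * len(spots)
        spike_mask = np.zeros_like(arr, dtype=bool)
        for i, j in spots:
            spike_mask[i, j] = True
        false_repl = np.sum((out != arr) & ~spike_mask)
        assert false_repl / arr.size < 0.001

    def test_despike_validates_window(self):
        with pytest.raises(ValueError):
            despike(np.zeros((5, 5)), window=4)


class TestFlankingGeometry:
    def test_default_gap(self):
        left, right = flanking_rois(ROI(10, 0, 4, 20))
        assert (left.x, right.x) == (6, 14)
        assert left.width == right.width == 4
        assert left.height == right.height == 20

    def test_gap_two(self):
        left, right = flanking_rois(ROI(10, 0, 4, 20), gap_px=2)
        assert (left.x, right.x) == (4, 16)

    def test_horizontal_vessel_flanks_vertically(self):
        top, bottom = flanking_rois(ROI(0, 10, 20, 4))
        assert (top.y, bottom.y) == (6, 14)

    def test_centered_roi_flanks_stay_inside_large_image(self):
        left, right = flanking_rois(ROI(40, 40, 4, 20), image_shape=(100, 100))
        assert not left.is_clipped_by((100, 100))
        assert not right.is_clipped_by((100, 100))

    def test_flank_fully_outside_raises(self):
        with pytest.raises(OutOfBoundsError):
            flanking_rois(ROI(0, 0, 4, 20), image_shape=(30, 6))


def _noiseless_vessel_scene(peak, diameter_px=6, seed=0):
    cam = COHORT_CAMERA
    d = diameter_px * cam.pixel_size_mm
    return SceneSpec(
        backlight_mean=1.0e6,
        backlight_rel_sd=0.0,
        vessels=(VesselSpec(((5.0, 2.0), (5.0, 14.0)), d, peak, "v"),),
        noise=NoiseSpec.noiseless(),
        seed=seed,
    ), cam


class TestVesselAttenuation:
    def test_definition(self):
        arr = np.ones((30, 30))
        arr[:, 12:16] = 0.9
        m = vessel_attenuation(arr, ROI(12, 5, 4, 20))
        assert m.attenuation == pytest.approx(0.10)
        assert m.flank_mean == pytest.approx(1.0)
        assert not m.negative_flagged

    def test_uniform_image_gives_zero(self):
        arr = np.full((30, 30), 4.2)
        m = vessel_attenuation(arr, ROI(12, 5, 4, 20))
        assert m.attenuation == pytest.approx(0.0)

    def test_negative_attenuation_flagged_not_clipped(self):
        arr = np.ones((30, 30))
        arr[:, 12:16] = 1.2  # vessel brighter than flanks
        m = vessel_attenuation(arr, ROI(12, 5, 4, 20))
        assert m.attenuation == pytest.approx(-0.2)
        assert m.negative_flagged

    def test_nonpositive_flanks_raise(self):
        arr = np.zeros((30, 30))
        with pytest.raises(NonPositiveReferenceError):
            vessel_attenuation(arr, ROI(12, 5, 4, 20))

    @given(c=st.floats(1e-3, 1e6))
    def test_scale_invariance(self, c):
        """Attenuation is a ratio statistic: rescaling the image is a no-op."""
        arr = np.ones((30, 30))
        arr[:, 12:16] = 0.88
        base = vessel_attenuation(arr, ROI(12, 5, 4, 20)).attenuation
        scaled = vessel_attenuation(c * arr, ROI(12, 5, 4, 20)).attenuation
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_offset_biases_toward_zero_and_subtraction_restores(self):
        scene, cam = _noiseless_vessel_scene(peak=0.12)
        img, _ = render_mouse(scene, cam)
        roi = vessel_measurement_roi(scene.vessels[0], cam)
        clean_att = vessel_attenuation(img, roi).attenuation
        offset = img.with_data(img.data + 0.5e6)
        biased_att = vessel_attenuation(offset, roi).attenuation
        assert biased_att < clean_att  # additive floor dilutes the ratio
        # a source-free background ROI outside the body support
        restored = subtract_background(offset, ROI(1, 1, 3, 3))
        assert vessel_attenuation(restored, roi).attenuation == pytest.approx(
            clean_att, abs=1e-9
        )

    def test_noiseless_bias_below_one_percent_absolute(self):
        """Strip-averaged truth (peak * pi/4) recovered to < 1 pp, no noise."""
        for peak in (0.05, 0.12, 0.2):
            scene, cam = _noiseless_vessel_scene(peak=peak)
            img, truth = render_mouse(scene, cam)
            roi = vessel_measurement_roi(scene.vessels[0], cam)
            m = vessel_attenuation(img, roi)
            assert m.attenuation == pytest.approx(
                truth.vessel_attenuations["v"], abs=0.01
            )

    def test_monotone_in_peak_and_diameter(self):
        """Dilated or darker vessels attenuate strictly more (noiseless)."""
        atts = []
        for peak in (0.04, 0.08, 0.12, 0.16):
            scene, cam = _noiseless_vessel_scene(peak=peak)
            img, _ = render_mouse(scene, cam)
            roi = vessel_measurement_roi(scene.vessels[0], cam)
            atts.append(vessel_attenuation(img, roi).attenuation)
        assert all(a < b for a, b in zip(atts, atts[1:]))

        by_diameter = []
        for d_px in (3, 6, 9):
            scene, cam = _noiseless_vessel_scene(peak=0.12, diameter_px=d_px)
            img, _ = render_mouse(scene, cam)
            # fixed ROI width: a wider vessel removes more light from it
            roi = ROI(57, 66, 6, 60, "v")
            by_diameter.append(vessel_attenuation(img, roi).attenuation)
        assert all(a < b for a, b in zip(by_diameter, by_diameter[1:]))


class TestRegionReduction:
    def test_definition(self):
        arr = np.ones((40, 40))
        arr[10:20, 10:20] = 0.79
        red = region_reduction(arr, ROI(10, 10, 10, 10), ROI(25, 25, 10, 10))
        assert red == pytest.approx(0.21)

    def test_identical_statistics_give_zero(self):
        arr = np.full((40, 40), 2.0)
        assert region_reduction(arr, ROI(0, 0, 10, 10), ROI(20, 20, 10, 10)) == 0.0

    def test_multiple_reference_rois_average(self):
        arr = np.ones((40, 40))
        arr[:, :20] = 2.0  # left half brighter
        target = ROI(18, 18, 4, 4)
        refs = [ROI(5, 18, 4, 4), ROI(30, 18, 4, 4)]  # means 2.0 and 1.0
        red = region_reduction(arr, target, refs)
        assert red == pytest.approx(1.0 - roi_mean(arr, target) / 1.5)

    def test_nonpositive_reference_raises(self):
        arr = np.zeros((20, 20))
        arr[2:6, 2:6] = 1.0
        with pytest.raises(NonPositiveReferenceError):
            region_reduction(arr, ROI(2, 2, 4, 4), ROI(10, 10, 4, 4))

    @given(c=st.floats(1e-3, 1e6))
    def test_scale_invariance(self, c):
        arr = np.ones((20, 20))
        arr[5:9, 5:9] = 0.7
        base = region_reduction(arr, ROI(5, 5, 4, 4), ROI(12, 12, 4, 4))
        assert region_reduction(c * arr, ROI(5, 5, 4, 4), ROI(12, 12, 4, 4)) == \
            pytest.approx(base, rel=1e-9)
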