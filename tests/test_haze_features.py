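"""Dark channel, airlight, transmission, contrast/entropy and sky features."""

import math

import numpy as np
import pytest

from hazepm.haze_features import (
    Airlight,
    FeatureConfig,
    dark_channel,
    estimate_airlight,
    extract_features,
    fit_extinction,
    image_entropy,
    rms_contrast,
    roi_transmissions,
    sky_color,
    sky_smoothness,
    transmission_map,
)
from hazepm.io_dataset import ROIBox
from hazepm.preprocess import SkyMask, to_gray
from hazepm.synth_scene import SceneSpec, render


def brute_force_dark_channel(img: np.ndarray, patch: int) -> np.ndarray:
    """Triple nested loop over pixels, window offsets and channels."""
    h, w, _ = img.shape
    r = patch // 2
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            lo_i, hi_i = max(0, i - r), min(h, i + r + 1)
            lo_j, hi_j = max(0, j - r), min(w, j + r + 1)
            best = math.inf
            for y in range(lo_i, hi_i):
                for x in range(lo_j, hi_j):
                    for c in range(3):
                        best = min(best, img[y, x, c])
            out[i, j] = best
    return out


class TestDarkChannel:
    def test_zero_blue_channel_gives_zero(self):
        img = np.random.default_rng(0).random((10, 10, 3))
        img[..., 2] = 0.0
        assert np.array_equal(dark_channel(img, 3), np.zeros((10, 10)))

    def test_constant_gray_is_fixed_point(self):
        img = np.full((8, 8, 3), 0.37)
        assert np.allclose(dark_channel(img, 5), 0.37)

    @pytest.mark.parametrize("patch", [1, 3, 5])
    def test_matches_brute_force(self, patch):
        rng = np.random.default_rng(11)
        for _ in range(5):
            img = rng.random((16, 16, 3))
            assert np.array_equal(dark_channel(img, patch), brute_force_dark_channel(img, patch))

    def test_never_exceeds_pointwise_channel_min(self):
        img = np.random.default_rng(12).random((20, 20, 3))
        assert np.all(dark_channel(img, 7) <= img.min(axis=-1) + 1e-15)

    def test_even_patch_rejected(self):
        with pytest.raises(ValueError):
            dark_channel(np.zeros((4, 4, 3)), 4)


class TestAirlight:
    def test_uniform_sky_recovered_exactly(self):
        img = np.full((30, 30, 3), 0.3)
        img[:10] = (0.80, 0.85, 0.95)
        sky = SkyMask(np.arange(30)[:, None] < 10 * np.ones((30, 30), dtype=bool))
        a = estimate_airlight(img, dark_channel(img, 3), sky)
        assert (a.a_r, a.a_g, a.a_b) == pytest.approx((0.80, 0.85, 0.95), abs=1e-12)

    def test_empty_sky_falls_back_to_global_brightest(self):
        img = np.full((20, 20, 3), 0.2)
        img[15:18, 15:18] = 0.9
        sky = SkyMask(np.zeros((20, 20), dtype=bool))
        a = estimate_airlight(img, dark_channel(img, 1), sky)
        assert a.a_r == pytest.approx(0.9)

    def test_rendered_scene_estimate_close_to_truth(self):
        scene = SceneSpec(airlight=(0.9, 0.9, 0.9))
        img, _ = render(scene, 6e-4)  # heavy haze
        a = estimate_airlight(img, dark_channel(img, 15), scene.true_sky_mask())
        for est, true in zip((a.a_r, a.a_g, a.a_b), scene.airlight):
            assert abs(est - true) <= 0.02

    def test_all_zero_image_rejected(self):
        img = np.zeros((5, 5, 3))
        with pytest.raises(ValueError):
            estimate_airlight(img, dark_channel(img, 1), None)

    def test_component_range_enforced(self):
        with pytest.raises(ValueError):
            Airlight(0.0, 0.5, 0.5)


class TestTransmissionMap:
    def test_image_equal_to_airlight_gives_zero(self):
        a = Airlight(0.7, 0.8, 0.9)
        img = np.tile(a.as_array(), (12, 12, 1))
        tm = transmission_map(img, a, 5)
        assert np.allclose(tm.values, 0.0)

    def test_zero_dark_channel_gives_one(self):
        img = np.random.default_rng(4).random((12, 12, 3))
        img[..., 0] = 0.0  # red channel is the anchor everywhere
        tm = transmission_map(img, Airlight(0.8, 0.8, 0.8), 3)
        assert np.allclose(tm.values, 1.0)

    def test_values_clipped_to_unit_interval(self):
        img = np.random.default_rng(5).random((16, 16, 3))
        tm = transmission_map(img, Airlight(0.5, 0.5, 0.5), 5)
        assert tm.values.min() >= 0.0 and tm.values.max() <= 1.0

    def test_forward_inverse_consistency_at_roi_centers(self):
        scene = SceneSpec()
        rois = scene.roi_boxes()
        for t_target in np.linspace(0.2, 0.9, 8):
            beta = -math.log(t_target) / scene.block_distances[-1]
            img, t_true = render(scene, beta)
            a = estimate_airlight(img, dark_channel(img, 15), scene.true_sky_mask())
            tm = transmission_map(img, a, 15)
            for b in rois:
                cy, cx = (b.top + b.bottom) // 2, (b.left + b.right) // 2
                assert abs(tm.values[cy, cx] - t_true[cy, cx]) <= 0.02


class TestROITransmissions:
    def test_constant_map(self):
        tm = transmission_map(
            np.full((20, 20, 3), 0.32), Airlight(0.8, 0.8, 0.8), 1
        )
        vals = roi_transmissions(tm, [ROIBox(2, 2, 10, 10)])
        assert vals[0] == pytest.approx(1 - 0.32 / 0.8)

    def test_piecewise_constant_halves(self):
        from hazepm.haze_features import TransmissionMap

        values = np.full((10, 20), 0.8)
        values[:, 10:] = 0.4
        tm = TransmissionMap(values, 1)
        out = roi_transmissions(tm, [ROIBox(0, 0, 10, 10), ROIBox(0, 10, 10, 20)])
        assert out == pytest.approx([0.8, 0.4])

    def test_matches_per_pixel_summation(self):
        from hazepm.haze_features import TransmissionMap

        rng = np.random.default_rng(6)
        values = rng.random((30, 40))
        tm = TransmissionMap(values, 1)
        boxes = [ROIBox(3, 5, 17, 21), ROIBox(10, 0, 30, 9)]
        expected = [
            sum(values[i, j] for i in range(b.top, b.bottom) for j in range(b.left, b.right))
            / ((b.bottom - b.top) * (b.right - b.left))
            for b in boxes
        ]
        assert roi_transmissions(tm, boxes) == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_box_rejected(self):
        from hazepm.haze_features import TransmissionMap

        tm = TransmissionMap(np.ones((10, 10)), 1)
        with pytest.raises(ValueError):
            roi_transmissions(tm, [ROIBox(0, 0, 12, 5)])


class TestExtinctionFit:
    def test_exact_exponential(self):
        d = np.array([1000.0, 2000.0, 3000.0, 4000.0])
        t = np.exp(-0.5 * d / 1000.0)
        fit = fit_extinction(t, d)
        assert fit.beta == pytest.approx(0.5e-3, rel=1e-12)
        assert fit.r2_loglinear == pytest.approx(1.0, abs=1e-12)

    def test_constant_transmission_zero_slope(self):
        fit = fit_extinction([0.6, 0.6, 0.6], [500.0, 1500.0, 3000.0])
        assert fit.beta == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_transmissions_excluded(self):
        fit = fit_extinction([0.9, 0.5, 0.0], [500.0, 2000.0, 4000.0])
        assert fit.beta > 0  # fitted on the two positive points only

    def test_single_usable_point_rejected(self):
        with pytest.raises(ValueError):
            fit_extinction([0.9, 0.0], [500.0, 2000.0])

    def test_recovers_beta_across_grid(self):
        scene = SceneSpec()
        rois = scene.roi_boxes()
        dists = [b.distance for b in rois]
        for beta in np.linspace(2e-5, 5.5e-4, 10):
            img, _ = render(scene, beta)
            a = estimate_airlight(img, dark_channel(img, 15), scene.true_sky_mask())
            tm = transmission_map(img, a, 15)
            fit = fit_extinction(roi_transmissions(tm, rois), dists)
            assert abs(fit.beta - beta) / beta <= 0.02


class TestScalarFeatures:
    def test_rms_contrast_constant_zero(self):
        assert rms_contrast(np.full((5, 5), 0.4)) == pytest.approx(0.0, abs=1e-15)

    def test_rms_contrast_two_level(self):
        assert rms_contrast(np.array([[0.0, 0.0], [1.0, 1.0]])) == pytest.approx(0.5)

    def test_rms_contrast_matches_summation(self):
        rng = np.random.default_rng(8)
        gray = rng.random((25, 25))
        mean = gray.sum() / gray.size
        expected = math.sqrt(((gray - mean) ** 2).sum() / gray.size)
        assert rms_contrast(gray) == pytest.approx(expected, abs=1e-12)

    def test_entropy_constant_zero(self):
        assert image_entropy(np.full((6, 6), 0.7)) == 0.0

    def test_entropy_uniform_histogram_is_log2_bins(self):
        gray = (np.arange(256).reshape(16, 16) + 0.5) / 256.0
        assert image_entropy(gray, bins=256) == pytest.approx(8.0)

    def test_entropy_two_equal_levels_is_one_bit(self):
        gray = np.array([[0.1, 0.9], [0.9, 0.1]])
        assert image_entropy(gray) == pytest.approx(1.0)

    def test_sky_color_uniform(self):
        img = np.tile(np.array([0.2, 0.3, 0.9]), (10, 10, 1))
        sky = SkyMask(np.ones((10, 10), dtype=bool))
        assert sky_color(img, sky) == pytest.approx(0.9)

    def test_sky_color_empty_mask_is_missing(self):
        img = np.ones((5, 5, 3))
        assert math.isnan(sky_color(img, SkyMask(np.zeros((5, 5), dtype=bool))))

    def test_sky_color_matches_masked_summation(self):
        rng = np.random.default_rng(9)
        img = rng.random((12, 12, 3))
        mask = rng.random((12, 12)) > 0.5
        expected = img[..., 2][mask].sum() / mask.sum()
        assert sky_color(img, SkyMask(mask)) == pytest.approx(expected, abs=1e-12)


class TestSkySmoothness:
    def test_constant_sky_zero(self):
        gray = np.full((10, 10), 0.8)
        mask = SkyMask(np.ones((10, 10), dtype=bool))
        assert sky_smoothness(gray, mask) == 0.0

    def test_linear_ramp_returns_slope(self):
        g = 0.01
        gray = np.tile(np.arange(20) * g, (10, 1))
        mask = SkyMask(np.ones((10, 20), dtype=bool))
        assert sky_smoothness(gray, mask) == pytest.approx(g, abs=1e-12)

    def test_textured_sky_rougher_than_flat(self):
        flat = SceneSpec(cloud_amplitude=0.0)
        cloudy = SceneSpec(cloud_amplitude=0.15)
        mask = flat.true_sky_mask()
        img_flat, _ = render(flat, 1e-4)
        img_cloudy, _ = render(cloudy, 1e-4)
        s_flat = sky_smoothness(to_gray(img_flat), mask)
        s_cloudy = sky_smoothness(to_gray(img_cloudy), mask)
        assert s_cloudy > s_flat

    def test_empty_mask_is_missing(self):
        gray = np.ones((5, 5))
        assert math.isnan(sky_smoothness(gray, SkyMask(np.zeros((5, 5), dtype=bool))))


class TestExtractFeatures:
    def test_clean_scene_transmission_near_one(self, sample_record, default_scene):
        img, _ = render(default_scene, 0.0)
        fv = extract_features(sample_record, default_scene.roi_boxes(), image=img)
        assert fv.transmission >= 0.95

    def test_heavy_haze_degenerates_contrast_and_entropy(self, sample_record, default_scene):
        img_clean, _ = render(default_scene, 0.0)
        img_hazy, _ = render(default_scene, 5e-3)  # t < 0.1 even at 500 m
        fv_clean = extract_features(sample_record, default_scene.roi_boxes(), image=img_clean)
        fv_hazy = extract_features(sample_record, default_scene.roi_boxes(), image=img_hazy)
        assert fv_hazy.image_contrast < 0.2 * fv_clean.image_contrast
        assert fv_hazy.image_entropy < 0.5 * fv_clean.image_entropy

    def test_deterministic(self, sample_record, default_scene):
        img, _ = render(default_scene, 2e-4)
        a = extract_features(sample_record, default_scene.roi_boxes(), image=img)
        b = extract_features(sample_record, default_scene.roi_boxes(), image=img)
        assert a.as_array() == pytest.approx(b.as_array(), abs=0, nan_ok=True)

    def test_feature_ranges(self, sample_record, default_scene):
        img, _ = render(default_scene, 2e-4)
        fv = extract_features(sample_record, default_scene.roi_boxes(), image=img)
        assert 0.0 <= fv.transmission <= 1.0
        assert fv.roi_contrast >= 0.0
        assert 0.0 <= fv.image_entropy <= 8.0
        assert 0.0 <= fv.sky_color <= 1.0
        assert 0.0 <= fv.solar_zenith <= 180.0
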