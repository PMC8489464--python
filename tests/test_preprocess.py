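"""Preprocessing: resampling, pad/crop, bias-field correction, augmentation."""

import numpy as np
import pytest

import cardiomark as cm
from cardiomark.core import Image2D, LandmarkSet
from cardiomark.preprocess import (
    PreprocessConfig,
    affine_about_center,
    augment,
    correct_inhomogeneity,
    estimate_bias_field,
    pad_or_crop,
    resample_to_spacing,
    to_detector_grid,
)


class TestResample:
    def test_integer_upscale(self):
        img = Image2D(np.random.default_rng(0).random((200, 200)), spacing=2.0)
        out, m = resample_to_spacing(img, 1.0)
        assert out.shape == (400, 400)
        assert out.spacing == 1.0
        np.testing.assert_allclose(m.apply([[50, 70]]), [[100, 140]])

    def test_identity(self):
        img = Image2D(np.random.default_rng(1).random((64, 64)), spacing=1.0)
        out, m = resample_to_spacing(img, 1.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)
        np.testing.assert_allclose(m.apply([[10, 12]]), [[10, 12]])

    def test_round_half_even_output_size(self):
        img = Image2D(np.zeros((300, 256)), spacing=1.4)
        out, _ = resample_to_spacing(img, 1.0)
        assert out.shape == (420, 358)  # 300*1.4 = 420.0; 256*1.4 = 358.4 -> 358

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(cm.ConfigurationError):
            resample_to_spacing(Image2D(np.zeros((32, 32))), 0.0)


class TestPadOrCrop:
    def test_identity(self):
        img = Image2D(np.random.default_rng(2).random((400, 400)))
        out, m = pad_or_crop(img, (400, 400))
        np.testing.assert_array_equal(out.pixels, img.pixels)
        assert m.offset == (0.0, 0.0)

    def test_pad_centers_content(self):
        img = Image2D(np.ones((100, 100)))
        out, m = pad_or_crop(img, (400, 400))
        assert out.shape == (400, 400)
        assert out.pixels[150:250, 150:250].all()
        assert out.pixels.sum() == 100 * 100
        np.testing.assert_allclose(m.apply([[0, 0]]), [[150, 150]])

    def test_mixed_crop_and_pad(self):
        img = Image2D(np.arange(420 * 358, dtype=float).reshape(420, 358))
        out, m = pad_or_crop(img, (400, 400))
        assert out.shape == (400, 400)
        # rows cropped 10 each side, cols padded 21 both sides
        np.testing.assert_array_equal(out.pixels[:, 21:379], img.pixels[10:410, :])
        assert (out.pixels[:, :21] == 0).all() and (out.pixels[:, 379:] == 0).all()
        np.testing.assert_allclose(m.apply([[10, 0]]), [[0, 21]])

    def test_odd_margins_take_extra_from_high_side(self):
        img = Image2D(np.ones((7, 5)))
        out, m = pad_or_crop(img, (4, 8))
        # rows: crop floor(3/2)=1 low, 2 high; cols: pad floor(3/2)=1 low, 2 high
        assert out.shape == (4, 8)
        np.testing.assert_allclose(m.apply([[1, 0]]), [[0, 1]])


class TestCoordinateMapComposition:
    def test_landmark_transform_matches_image_transform(self):
        # place a Gaussian blob at a landmark, push the image through the
        # grid pipeline, and check the blob's peak lands where the composed
        # map sends the landmark
        lm = LandmarkSet("SAX", [[30, 40], [np.nan] * 2, [np.nan] * 2], [True, False, False])
        blob = cm.encode(lm, (100, 100), 3.0).probs[:, :, 1]
        img = Image2D(blob, spacing=2.0)
        cfg = PreprocessConfig(target_spacing=1.0, target_size=(256, 256))
        gridded, m = to_detector_grid(img, cfg)
        mapped = m.apply([[30, 40]])[0]
        peak = np.unravel_index(np.argmax(gridded.pixels), gridded.shape)
        assert np.abs(np.asarray(peak) - mapped).max() <= 1.0

    def test_inverse_roundtrip(self):
        m = cm.CoordinateMap((2.0, 1.5), (10.0, -4.0))
        pts = np.array([[3.0, 7.0], [0.0, 0.0]])
        np.testing.assert_allclose(m.inverse().apply(m.apply(pts)), pts)


class TestBiasField:
    def test_constant_image_gives_flat_field(self):
        field = estimate_bias_field(Image2D(np.full((64, 64), 3.0)))
        np.testing.assert_allclose(field, 1.0, atol=1e-9)

    def test_recovers_smooth_ramp(self):
        rr = np.linspace(0.6, 1.0, 96)[:, None] * np.ones((1, 96))
        field_true = rr / rr.max()
        img = Image2D(np.full((96, 96), 2.0) * field_true)
        est = estimate_bias_field(img)
        rel = np.abs(est - field_true) / field_true
        assert rel.max() < 0.10

    def test_all_zero_image_gives_ones(self):
        np.testing.assert_array_equal(estimate_bias_field(Image2D(np.zeros((32, 32)))), 1.0)

    def test_field_floored(self):
        img = Image2D(np.eye(64) * 1000.0)
        field = estimate_bias_field(img, intensity_floor=1e-3)
        assert field.min() >= 1e-3


class TestCorrectInhomogeneity:
    def test_flat_field_is_identity(self):
        img = Image2D(np.random.default_rng(3).random((32, 32)) + 0.5)
        out = correct_inhomogeneity(img, np.ones((32, 32)))
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=1e-12)

    def test_mean_preserved(self):
        rng = np.random.default_rng(4)
        img = Image2D(rng.random((48, 48)) + 0.2)
        field = estimate_bias_field(img)
        out = correct_inhomogeneity(img, field)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(), rel=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            correct_inhomogeneity(Image2D(np.ones((32, 32))), np.ones((16, 16)))

    def test_idempotent_within_one_percent(self):
        cfg = cm.PhantomConfig(view="SAX", noise_sd=0.0, shading_amplitude=0.5).scaled_to((96, 96))
        s = cm.generate_short_axis(cfg, np.random.default_rng(9))
        once = correct_inhomogeneity(s.image, estimate_bias_field(s.image))
        twice = correct_inhomogeneity(once, estimate_bias_field(once))
        rel = np.abs(twice.pixels - once.pixels) / (np.abs(once.pixels) + 1e-6)
        assert np.median(rel) < 0.01


class TestAugment:
    def _sample(self):
        cfg = cm.PhantomConfig(view="CH2").scaled_to((64, 64))
        s = cm.generate_long_axis(cfg, np.random.default_rng(6))
        return s.image, s.landmarks

    def test_identity_parameters_unchanged(self):
        img, lms = self._sample()
        out_img, out_lms = affine_about_center(img, lms, 0.0, 1.0, (0.0, 0.0))
        np.testing.assert_array_equal(out_img.pixels, img.pixels)
        np.testing.assert_array_equal(out_lms.coords, lms.coords)

    def test_quarter_turn_coordinates(self):
        img = Image2D(np.zeros((400, 400)))
        lms = LandmarkSet("SAX", [[100, 100], [np.nan] * 2, [np.nan] * 2], [True, False, False])
        _, out = affine_about_center(img, lms, 90.0, 1.0, (0.0, 0.0))
        np.testing.assert_allclose(out.coords[0], [100.0, 299.0], atol=1e-9)

    def test_rotation_moves_image_with_landmarks(self):
        lm = LandmarkSet("SAX", [[20, 40], [np.nan] * 2, [np.nan] * 2], [True, False, False])
        blob = cm.encode(lm, (64, 64), 2.5).probs[:, :, 1]
        img = Image2D(blob)
        out_img, out_lm = affine_about_center(img, lm, 30.0, 1.05, (3.0, -2.0))
        peak = np.unravel_index(np.argmax(out_img.pixels), out_img.shape)
        assert np.abs(np.asarray(peak) - out_lm.coords[0]).max() <= 1.0

    def test_out_of_bounds_landmark_marked_absent(self):
        img = Image2D(np.zeros((64, 64)))
        lms = LandmarkSet("SAX", [[2, 2], [32, 32], [60, 60]], [True, True, True])
        _, out = affine_about_center(img, lms, 0.0, 1.0, (-10.0, 0.0))
        assert not out.present[0]
        assert out.present[1]

    def test_fixed_seed_reproducible(self):
        img, lms = self._sample()
        cfg = PreprocessConfig(target_size=(64, 64))
        a = augment(img, lms, cfg, np.random.default_rng(5))
        b = augment(img, lms, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].coords, b[1].coords)
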