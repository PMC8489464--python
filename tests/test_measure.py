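"""Geometry closed forms and evaluation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardiomark as cm
from cardiomark.core import DetectionResult, LandmarkSet, UndefinedMeasurementError
from cardiomark.measure import (
    a_rvi_angle,
    detection_rate,
    euclidean_distance_mm,
    lv_length,
    lv_length_of,
    shortening_curve,
)


class TestDistance:
    def test_three_four_five(self):
        assert euclidean_distance_mm((0, 0), (3, 4), 1.0) == 5.0

    def test_identical_points(self):
        assert euclidean_distance_mm((7, 2), (7, 2), 1.0) == 0.0

    def test_spacing_scales_linearly(self):
        assert euclidean_distance_mm((0, 0), (3, 4), 2.0) == 10.0

    def test_nonfinite_rejected(self):
        with pytest.raises(UndefinedMeasurementError):
            euclidean_distance_mm((np.nan, 0), (0, 0), 1.0)


class TestLVLength:
    def test_midpoint_construction(self):
        assert lv_length((0, 0), (30, 8), (30, -8), 1.0) == 30.0

    def test_apex_at_midpoint_is_zero(self):
        assert lv_length((30, 0), (30, 8), (30, -8), 1.0) == 0.0

    def test_valve_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            apex, va, vb = rng.uniform(0, 100, (3, 2))
            assert lv_length(apex, va, vb, 1.0) == pytest.approx(
                lv_length(apex, vb, va, 1.0), rel=1e-12
            )

    def test_absent_landmark_signals_undefined(self):
        lm = LandmarkSet("CH2", [[10, 10], [np.nan, np.nan], [50, 50]], [True, False, True])
        with pytest.raises(UndefinedMeasurementError):
            lv_length_of(lm)

    def test_matches_phantom_ground_truth(self):
        cfg = cm.PhantomConfig(view="CH3", landmark_jitter_sd=0.0).scaled_to((96, 96))
        rng = np.random.default_rng(4)
        for _ in range(10):
            s = cm.generate_long_axis(cfg, rng)
            assert lv_length_of(s.landmarks, s.image.spacing) == pytest.approx(
                s.params["lv_length_mm"], abs=1.0 * s.image.spacing
            )


class TestAngle:
    def test_along_positive_col_axis(self):
        assert a_rvi_angle((100, 140), (100, 100)) == 0.0

    def test_up_the_image_is_ninety(self):
        assert a_rvi_angle((60, 100), (100, 100)) == 90.0

    def test_diagonal_is_forty_five(self):
        assert a_rvi_angle((60, 140), (100, 100)) == 45.0

    def test_coincident_points_undefined(self):
        with pytest.raises(UndefinedMeasurementError):
            a_rvi_angle((10, 10), (10, 10))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rotation_consistency(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(20, 80, 2)
        a = c + rng.uniform(-15, 15, 2)
        if np.allclose(a, c):
            a = c + np.array([5.0, 5.0])
        theta = rng.uniform(0, 360)
        base = a_rvi_angle(a, c)
        # rotate the A-RVI about C-LV by theta (counterclockwise in the
        # angle's own frame)
        rad = np.radians(theta)
        dr, dc = a - c
        x, y = dc, -dr  # to math (x, y)
        xr = x * np.cos(rad) - y * np.sin(rad)
        yr = x * np.sin(rad) + y * np.cos(rad)
        rotated = c + np.array([-yr, xr])
        assert a_rvi_angle(rotated, c) == pytest.approx((base + theta) % 360, abs=1e-6)


class TestShorteningCurve:
    def _series(self, lengths):
        out = []
        for L in lengths:
            out.append(LandmarkSet("CH2", [[0, 8], [0, -8], [L, 0]], [True, True, True]))
        return out

    def test_constant_series_all_zero(self):
        np.testing.assert_allclose(shortening_curve(self._series([50, 50, 50])), 0.0)

    def test_first_phase_ratio_zero_by_definition(self):
        curve = shortening_curve(self._series([50, 45, 40, 45]))
        assert curve[0] == 0.0
        np.testing.assert_allclose(curve, [0.0, 0.1, 0.2, 0.1])

    def test_missing_phase_yields_gap(self):
        series = self._series([50, 45, 40])
        series[1] = LandmarkSet("CH2", [[0, 8], [np.nan, np.nan], [45, 0]],
                                [True, False, True])
        curve = shortening_curve(series)
        assert np.isnan(curve[1]) and curve[2] == pytest.approx(0.2)

    def test_phantom_cine_peak_matches_contraction_fraction(self):
        cfg = cm.PhantomConfig(view="CH2", landmark_jitter_sd=0.0).scaled_to((96, 96))
        series = cm.generate_cine_series(cfg, 20, 0.2, np.random.default_rng(7))
        curve = shortening_curve([s.landmarks for s in series], 1.0)
        assert curve.max() == pytest.approx(0.2, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            shortening_curve(self._series([50]))
        bad = self._series([50, 45])
        bad[0] = LandmarkSet.absent("CH2")
        with pytest.raises(UndefinedMeasurementError):
            shortening_curve(bad)


def _pair(all_found: bool, view="SAX"):
    truth = LandmarkSet.from_points(view, [[10, 10], [30, 30], [20, 40]])
    present = np.array([True, True, all_found])
    coords = truth.coords + 0.5
    det = DetectionResult(view, present, coords, present.astype(float))
    return det, truth


class TestDetectionRate:
    def test_large_cohort_rate_rounds_to_printed_precision(self):
        # 2072 of 2076 images with all landmarks found reads as 99.8%
        results = [_pair(True)] * 2072 + [_pair(False)] * 4
        rep = detection_rate(results)
        assert round(rep.detection_rate, 1) == 99.8

    def test_all_perfect(self):
        results = [_pair(True) for _ in range(10)]
        rep = detection_rate(results)
        assert rep.detection_rate == 100.0
        assert rep.false_positives == 0

    def test_nine_of_ten(self):
        results = [_pair(True)] * 9 + [_pair(False)]
        assert detection_rate(results).detection_rate == 90.0

    def test_order_invariance(self):
        results = [_pair(True)] * 7 + [_pair(False)] * 3
        a = detection_rate(results)
        b = detection_rate(results[::-1])
        assert a.detection_rate == b.detection_rate
        assert a.per_landmark["n"].tolist() == b.per_landmark["n"].tolist()

    def test_distances_exclude_failed_detections(self):
        det, truth = _pair(False)
        rep = detection_rate([(det, truth)])
        roles = set(rep.per_landmark["role"])
        assert "C-LV" not in roles  # third role undetected -> excluded
        np.testing.assert_allclose(rep.per_landmark["mean_mm"], np.hypot(0.5, 0.5))

    def test_distances_scale_with_spacing(self):
        results = [_pair(True)]
        a = detection_rate(results, spacing=1.0)
        b = detection_rate(results, spacing=2.0)
        np.testing.assert_allclose(
            b.per_landmark["mean_mm"], 2 * a.per_landmark["mean_mm"]
        )
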