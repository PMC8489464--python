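"""Derived clinical measurements and detector evaluation statistics.

Measurements operate in the package's (row, col) pixel frame and convert to
millimetres via the pixel spacing:

* **LV length** — distance from the apical point to the midpoint of the two
  valve points on a long-axis view.
* **RV-insertion angle** — the angle of the vector from the LV center
  (C-LV) to the anterior RV-insertion point (A-RVI), measured
  counterclockwise from the +col axis (row axis pointing down), in
  [0, 360).  The reference frame is an explicit choice and is recorded in
  report metadata.
* **longitudinal shortening curve** — per cardiac phase,
  ``(L(1) - L(t)) / L(1)`` with phase 1 (end-diastole) as baseline.

Evaluation summarizes detections against reference annotations: the
detection (success) rate is the percentage of images on which every
truth-present landmark was found; Euclidean distances are reported as mean
+/- SD over successful detections only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DetectionResult, LandmarkSet, UndefinedMeasurementError
from .heatmap import count_errors

ANGLE_FRAME = "counterclockwise from +col axis, row axis pointing down"


def euclidean_distance_mm(p, q, spacing: float = 1.0) -> float:
    """``spacing * sqrt(drow^2 + dcol^2)`` between two pixel points."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise UndefinedMeasurementError("distance requires finite points")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return float(spacing * np.hypot(*(p - q)))


def lv_length(apex, valve_a, valve_b, spacing: float = 1.0) -> float:
    """Apex to mid-valve-plane distance in millimetres."""
    va = np.asarray(valve_a, dtype=np.float64)
    vb = np.asarray(valve_b, dtype=np.float64)
    if not (np.all(np.isfinite(va)) and np.all(np.isfinite(vb))):
        raise UndefinedMeasurementError("LV length requires both valve points")
    return euclidean_distance_mm(apex, (va + vb) / 2.0, spacing)


def lv_length_of(landmarks: LandmarkSet | DetectionResult, spacing: float | None = None) -> float:
    """LV length from a long-axis landmark set (roles: valve, valve, apex)."""
    lm = landmarks.to_landmark_set() if isinstance(landmarks, DetectionResult) else landmarks
    if lm.view == "SAX":
        raise UndefinedMeasurementError("LV length is a long-axis measurement")
    if not lm.present.all():
        raise UndefinedMeasurementError("LV length requires all three landmarks")
    sp = 1.0 if spacing is None else spacing
    return lv_length(lm.coords[2], lm.coords[0], lm.coords[1], sp)


def a_rvi_angle(a_rvi, c_lv) -> float:
    """Angle of the C-LV -> A-RVI vector in degrees, in [0, 360).

    Zero points along +col; 90 degrees points up the image (toward smaller
    row indices), i.e. the angle grows counterclockwise in the displayed
    frame.
    """
    a = np.asarray(a_rvi, dtype=np.float64)
    c = np.asarray(c_lv, dtype=np.float64)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(c))):
        raise UndefinedMeasurementError("angle requires both points present")
    dr, dc = a - c
    if dr == 0.0 and dc == 0.0:
        raise UndefinedMeasurementError("A-RVI and C-LV coincide; angle undefined")
    return float(math.degrees(math.atan2(-dr, dc)) % 360.0)


def shortening_curve(
    series: list[DetectionResult] | list[LandmarkSet], spacing: float = 1.0
) -> np.ndarray:
    """Global longitudinal shortening ratio per phase, baseline = phase 1.

    Phases with missing landmarks yield NaN gaps; the first phase must have
    all landmarks present and a nonzero LV length.
    """
    if len(series) < 2:
        raise ValueError("a cine series needs at least 2 phases")
    lengths = []
    for det in series:
        try:
            lengths.append(lv_length_of(det, spacing))
        except UndefinedMeasurementError:
            lengths.append(np.nan)
    if not np.isfinite(lengths[0]):
        raise UndefinedMeasurementError("all landmarks must be present in phase 1")
    if lengths[0] == 0.0:
        raise ValueError("baseline LV length is zero")
    L = np.asarray(lengths)
    return (L[0] - L) / L[0]


@dataclass
class EvalReport:
    """Detection-rate and distance summary against reference annotations."""

    n_images: int
    n_all_detected: int
    false_positives: int
    per_landmark: pd.DataFrame  # view, role, n, mean_mm, sd_mm
    meta: dict = field(default_factory=lambda: {"angle_frame": ANGLE_FRAME})

    @property
    def detection_rate(self) -> float:
        """Percent of images with every truth-present landmark detected."""
        return 100.0 * self.n_all_detected / self.n_images

    def to_text(self) -> str:
        lines = [
            f"images: {self.n_images}",
            f"detection rate: {self.detection_rate:.1f}% "
            f"({self.n_all_detected} of {self.n_images} images)",
            f"false positives: {self.false_positives}",
            "",
            self.per_landmark.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.per_landmark.to_csv(path, index=False)


def detection_rate(
    results: list[tuple[DetectionResult, LandmarkSet]], spacing: float = 1.0
) -> EvalReport:
    """Aggregate detection statistics over (prediction, truth) pairs.

    The rate counts images where all truth-present landmarks were detected;
    per-landmark Euclidean distances (mean +/- SD, mm) are pooled over
    successful detections only.
    """
    if not results:
        raise ValueError("results list is empty")
    n_all, fp = 0, 0
    dists: dict[tuple[str, str], list[float]] = {}
    for pred, truth in results:
        missed, spurious, all_det = count_errors(pred, truth)
        fp += spurious
        n_all += int(all_det)
        for k, role in enumerate(truth.roles):
            if truth.present[k] and pred.present[k]:
                d = euclidean_distance_mm(pred.coords[k], truth.coords[k], spacing)
                dists.setdefault((truth.view, role), []).append(d)
    rows = [
        {
            "view": view,
            "role": role,
            "n": len(v),
            "mean_mm": float(np.mean(v)),
            "sd_mm": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
        for (view, role), v in sorted(dists.items())
    ]
    df = pd.DataFrame(rows, columns=["view", "role", "n", "mean_mm", "sd_mm"])
    return EvalReport(len(results), n_all, fp, df)


def mean_landmark_error(
    results: list[tuple[DetectionResult, LandmarkSet]], spacing: float = 1.0
) -> float:
    """Mean Euclidean error (mm) pooled over all successful detections."""
    report = detection_rate(results, spacing)
    if report.per_landmark.empty:
        return float("nan")
    n = report.per_landmark["n"]
    return float((report.per_landmark["mean_mm"] * n).sum() / n.sum())
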