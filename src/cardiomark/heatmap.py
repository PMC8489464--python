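"""Landmark <-> heatmap conversion and decoding with presence decisions.

Detecting L landmarks on an image is recast as semantic segmentation over
L + 1 classes: channel 0 is background and channel k >= 1 carries the spatial
probability of landmark k, obtained by convolving the point annotation with
an isotropic Gaussian kernel (default sigma = 4 px).  Per pixel the channels
are normalized to a proper class distribution so entropy-based losses apply.

Decoding inverts the encoding: each landmark channel is scanned for its peak;
the landmark is declared present when the peak probability reaches the
presence threshold, and its coordinate is refined to subpixel precision by a
probability-weighted centroid around the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, DetectionResult, LandmarkSet, VIEW_ROLES


@dataclass
class Heatmap:
    """Per-pixel class distribution over background + L landmarks.

    ``probs`` has shape ``(rows, cols, L + 1)``; channel 0 is background,
    channels 1..L the landmarks in the role order of the view.
    """

    probs: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3:
            raise ValueError("heatmap must be rows x cols x channels")

    @property
    def n_landmarks(self) -> int:
        return self.probs.shape[2] - 1


@dataclass
class DecodeConfig:
    """Decoding rule: presence threshold and subpixel-centroid window.

    ``subpixel_window`` defaults to twice the encoding sigma when None.
    """

    presence_threshold: float = 0.5
    subpixel_window: float | None = None
    sigma: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.presence_threshold < 1.0:
            raise ConfigurationError("presence_threshold must be in (0, 1)")
        if self.subpixel_window is None:
            self.subpixel_window = 2.0 * self.sigma
        if self.subpixel_window <= 0:
            raise ConfigurationError("subpixel_window must be positive")


def encode(landmarks: LandmarkSet, shape: tuple[int, int], sigma: float = 4.0) -> Heatmap:
    """Encode a landmark set as a per-pixel class distribution.

    Each present landmark contributes ``exp(-d^2 / (2 sigma^2))`` (peak 1 at
    the landmark); absent landmarks contribute a zero channel.  The
    background channel is ``clamp(1 - sum(landmark channels), 0, 1)`` and the
    stack is renormalized per pixel, so every pixel sums to one while the
    landmark channel's maximum stays at the pixel nearest the annotation.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ConfigurationError("shape must be positive")
    L = landmarks.n_landmarks
    chans = np.zeros((rows, cols, L + 1), dtype=np.float64)
    rr = np.arange(rows, dtype=np.float64)[:, None]
    cc = np.arange(cols, dtype=np.float64)[None, :]
    for k in range(L):
        if not landmarks.present[k]:
            continue
        r0, c0 = landmarks.coords[k]
        if not (0.0 <= r0 <= rows - 1 and 0.0 <= c0 <= cols - 1):
            raise ValueError(
                f"landmark {landmarks.roles[k]!r} at ({r0:.1f}, {c0:.1f}) lies outside {shape}"
            )
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        chans[:, :, k + 1] = np.exp(-d2 / (2.0 * sigma**2))
    fg = chans[:, :, 1:].sum(axis=2)
    chans[:, :, 0] = np.clip(1.0 - fg, 0.0, 1.0)
    chans /= chans.sum(axis=2, keepdims=True)
    return Heatmap(chans, sigma)


def decode(
    probs: np.ndarray | Heatmap,
    view: str,
    config: DecodeConfig | None = None,
) -> DetectionResult:
    """Decode a predicted probability stack into landmark detections.

    Per landmark channel the global maximum is located (ties broken by the
    smallest row-major index); the landmark is present iff the peak
    probability is at least the presence threshold.  Present landmarks are
    refined to subpixel precision by a separable quadratic fit to the log
    probabilities of the peak's immediate neighbours — exact for sampled
    Gaussian peaks of any width — falling back to a probability-weighted
    centroid over a window of half-width ``subpixel_window`` when the log
    fit is unusable (zero or non-concave neighbours).
    """
    if config is None:
        config = DecodeConfig()
    arr = probs.probs if isinstance(probs, Heatmap) else np.asarray(probs, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] < 2:
        raise ValueError("expected a rows x cols x channels probability stack")
    if not np.all(np.isfinite(arr)):
        raise ValueError("probability grid contains non-finite values")
    sums = arr.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("per-pixel channel sums must be ~1 (softmax the scores first)")
    n_roles = len(VIEW_ROLES[view])
    if arr.shape[2] != n_roles + 1:
        raise ValueError(f"view {view} expects {n_roles + 1} channels, got {arr.shape[2]}")

    rows, cols = arr.shape[:2]
    w = int(round(config.subpixel_window))
    present = np.zeros(n_roles, bool)
    coords = np.full((n_roles, 2), np.nan)
    peaks = np.zeros(n_roles)
    for k in range(n_roles):
        ch = arr[:, :, k + 1]
        flat = int(np.argmax(ch))  # row-major: smallest index wins ties
        pr, pc = divmod(flat, cols)
        peak = ch[pr, pc]
        peaks[k] = peak
        if peak < config.presence_threshold:
            continue
        present[k] = True
        dr = _log_parabolic_offset(ch[max(0, pr - 1) : pr + 2, pc], 1 if pr > 0 else 0)
        dc = _log_parabolic_offset(ch[pr, max(0, pc - 1) : pc + 2], 1 if pc > 0 else 0)
        if dr is not None and dc is not None:
            coords[k] = (pr + dr, pc + dc)
        else:
            r0, r1 = max(0, pr - w), min(rows, pr + w + 1)
            c0, c1 = max(0, pc - w), min(cols, pc + w + 1)
            win = ch[r0:r1, c0:c1]
            total = win.sum()
            if total <= 0:
                coords[k] = (pr, pc)
            else:
                rr = np.arange(r0, r1, dtype=np.float64)[:, None]
                cc = np.arange(c0, c1, dtype=np.float64)[None, :]
                coords[k] = ((rr * win).sum() / total, (cc * win).sum() / total)
    return DetectionResult(view, present, coords, peaks)


def _log_parabolic_offset(triple: np.ndarray, center: int) -> float | None:
    """Subpixel offset from a 3-point quadratic fit in log space.

    ``triple`` holds the channel values around the peak along one axis;
    returns the offset of the quadratic's vertex from the peak pixel,
    clipped to [-1, 1], or None when the fit is unusable (border peak,
    zero neighbours, or non-concave logs).
    """
    if len(triple) != 3 or center != 1:
        return 0.0 if len(triple) > 0 else None
    fm, f0, fp = triple
    if fm <= 0.0 or f0 <= 0.0 or fp <= 0.0:
        return None
    lm, l0, lp = np.log(fm), np.log(f0), np.log(fp)
    denom = lm - 2.0 * l0 + lp
    if denom >= 0.0:
        return None
    return float(np.clip((lm - lp) / (2.0 * denom), -1.0, 1.0))


def count_errors(
    pred: DetectionResult, truth: LandmarkSet
) -> tuple[int, int, bool]:
    """Missed / spurious landmark counts against a reference annotation.

    Returns ``(missed, spurious, all_detected)`` where ``all_detected`` is
    true iff every truth-present landmark was predicted present (vacuously
    true on landmark-free frames).
    """
    if pred.view != truth.view:
        raise ValueError(f"view mismatch: prediction {pred.view}, truth {truth.view}")
    missed = int(np.sum(truth.present & ~pred.present))
    spurious = int(np.sum(~truth.present & pred.present))
    return missed, spurious, missed == 0
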