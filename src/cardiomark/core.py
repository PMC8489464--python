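"""Core data containers shared across the package.

Coordinate convention
---------------------
All geometry lives in a single 0-based ``(row, col)`` pixel frame with pixel
centers at integer coordinates.  The row axis points *down* the image, the
col axis points right.  Physical lengths are obtained by multiplying pixel
distances by the (isotropic) pixel ``spacing`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Ordered landmark roles for every supported view.  The channel order of
#: heatmaps follows these tables (channel 0 is always background, channels
#: 1..3 the roles below, in order), so one long-axis model can serve the
#: two-, three- and four-chamber views interchangeably.
VIEW_ROLES: Mapping[str, tuple[str, str, str]] = {
    "CH2": ("anterior", "inferior", "apex"),
    "CH3": ("inferolateral", "anteroseptal", "apex"),
    "CH4": ("inferoseptal", "anterolateral", "apex"),
    "SAX": ("A-RVI", "P-RVI", "C-LV"),
}

LONG_AXIS_VIEWS = ("CH2", "CH3", "CH4")


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


class UndefinedMeasurementError(ValueError):
    """Raised when a derived measurement is requested from absent landmarks."""


@dataclass
class Image2D:
    """A 2D grayscale image with physical pixel spacing.

    Parameters
    ----------
    pixels
        2D array of non-negative finite intensities, shape ``(rows, cols)``.
    spacing
        Millimetres per pixel, assumed isotropic.
    meta
        Optional free-form tags (image id, view, ...).
    """

    pixels: np.ndarray
    spacing: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D pixel grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.spacing <= 0:
            raise ConfigurationError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LandmarkSet:
    """Ordered landmarks for one view: coordinates plus presence flags.

    ``coords`` is ``(3, 2)`` float (row, col); absent landmarks carry NaN
    coordinates and ``present=False``.
    """

    view: str
    coords: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        if self.view not in VIEW_ROLES:
            raise ConfigurationError(f"unknown view {self.view!r}; expected one of {sorted(VIEW_ROLES)}")
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        self.present = np.asarray(self.present, dtype=bool).reshape(-1)
        n = len(VIEW_ROLES[self.view])
        if self.coords.shape[0] != n or self.present.shape[0] != n:
            raise ValueError(f"view {self.view} expects {n} landmarks")
        if self.present.any() and not np.all(np.isfinite(self.coords[self.present])):
            raise ValueError("present landmarks must have finite coordinates")

    @property
    def roles(self) -> tuple[str, ...]:
        return VIEW_ROLES[self.view]

    @property
    def n_landmarks(self) -> int:
        return len(self.roles)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.view, self.coords.copy(), self.present.copy())

    @classmethod
    def absent(cls, view: str) -> "LandmarkSet":
        """A landmark-free frame for ``view`` (all flags false)."""
        n = len(VIEW_ROLES[view])
        return cls(view, np.full((n, 2), np.nan), np.zeros(n, bool))

    @classmethod
    def from_points(cls, view: str, points: Sequence[Sequence[float]]) -> "LandmarkSet":
        pts = np.asarray(points, dtype=np.float64)
        return cls(view, pts, np.ones(pts.shape[0], bool))

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        """True if every present landmark lies strictly inside ``shape``."""
        if not self.present.any():
            return True
        c = self.coords[self.present]
        return bool(
            np.all(c[:, 0] > 0) and np.all(c[:, 0] < shape[0] - 1)
            and np.all(c[:, 1] > 0) and np.all(c[:, 1] < shape[1] - 1)
        )


@dataclass
class DetectionResult:
    """Decoded landmark coordinates, peak probabilities and presence calls."""

    view: str
    present: np.ndarray
    coords: np.ndarray
    peak_probs: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        self.peak_probs = np.asarray(self.peak_probs, dtype=np.float64)

    @property
    def roles(self) -> tuple[str, ...]:
        return VIEW_ROLES[self.view]

    def to_landmark_set(self) -> LandmarkSet:
        coords = self.coords.copy()
        coords[~self.present] = np.nan
        return LandmarkSet(self.view, coords, self.present.copy())
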