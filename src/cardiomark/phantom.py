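"""Synthetic cardiac-style phantoms with known landmark ground truth.

The generator emulates the statistical structure a heatmap landmark detector
assumes in cardiac MR images, at desk scale and with exactly known geometry:

* **long-axis frames** (CH2/CH3/CH4): a bright, bullet-shaped ventricle
  silhouette with a darker myocardial rim; landmarks are the two valve points
  flanking the base and the apical point at the opposite pole.
* **short-axis frames** (SAX): a bright LV blood pool inside a darker
  myocardial annulus with an attached crescent-shaped RV cavity; landmarks
  are the anterior/posterior RV-insertion points at the crescent-annulus
  junctions and the LV center.  A configurable fraction of frames contain no
  landmarks at all (basal/apical slices beyond the ventricle).
* **cine series**: a smoothly contracting long-axis cycle whose ground-truth
  LV length shrinks to ``(1 - contraction_fraction)`` of the end-diastolic
  length at the mid-series end-systolic phase and recovers.

Appearance degradations mirror acquisition artifacts: a multiplicative
low-frequency shading field (surface-coil sensitivity), Rician-approximated
noise, and Gaussian annotation jitter emulating interreader variability.

Every sample records the sampled geometry parameters in
``PhantomSample.params`` so tests can verify ground-truth self-consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .core import (
    ConfigurationError,
    Image2D,
    LandmarkSet,
    LONG_AXIS_VIEWS,
    VIEW_ROLES,
)

_REFERENCE_SIZE = 96  # mm-ranges below are calibrated to a 96 px / 1 mm frame


@dataclass
class PhantomConfig:
    """Parameters of the synthetic phantom generator.

    Geometric ranges are in millimetres and are calibrated to the default
    96x96 frame at 1 mm spacing; :meth:`scaled_to` rescales them for other
    frame sizes so the anatomy keeps the same relative proportions.
    """

    image_size: tuple[int, int] = (96, 96)
    pixel_spacing: float = 1.0
    view: str = "SAX"
    lv_length_range: tuple[float, float] = (45.0, 65.0)
    lv_radius_range: tuple[float, float] = (14.0, 22.0)
    wall_thickness_range: tuple[float, float] = (5.0, 9.0)
    rv_crescent: bool = True
    shading_amplitude: float = 0.3
    noise_sd: float = 0.03
    landmark_jitter_sd: float = 0.5
    prob_no_landmark_frame: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in VIEW_ROLES:
            raise ConfigurationError(f"unknown view {self.view!r}")
        rows, cols = self.image_size
        if rows < 32 or cols < 32:
            raise ConfigurationError("image_size must be >= 32 in each dimension")
        if self.pixel_spacing <= 0:
            raise ConfigurationError("pixel_spacing must be positive")
        for name in ("lv_length_range", "lv_radius_range", "wall_thickness_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigurationError(f"{name} must satisfy 0 < min <= max")
        if not 0.0 <= self.shading_amplitude < 1.0:
            raise ConfigurationError("shading_amplitude must be in [0, 1)")
        if not 0.0 <= self.prob_no_landmark_frame <= 1.0:
            raise ConfigurationError("prob_no_landmark_frame must be in [0, 1]")
        if self.noise_sd < 0 or self.landmark_jitter_sd < 0:
            raise ConfigurationError("noise_sd and landmark_jitter_sd must be >= 0")

    def scaled_to(self, image_size: tuple[int, int]) -> "PhantomConfig":
        """The same anatomy proportionally rescaled to another frame size."""
        f = min(image_size) / _REFERENCE_SIZE * self.pixel_spacing
        scale = lambda r: (r[0] * f, r[1] * f)  # noqa: E731
        return replace(
            self,
            image_size=image_size,
            lv_length_range=scale(self.lv_length_range),
            lv_radius_range=scale(self.lv_radius_range),
            wall_thickness_range=scale(self.wall_thickness_range),
        )


@dataclass
class PhantomSample:
    """A synthetic image with its ground-truth landmarks and view tag."""

    image: Image2D
    landmarks: LandmarkSet
    view: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.landmarks.view != self.view:
            raise ValueError("landmarks.view must equal the sample view")


def _as_rng(rng: np.random.Generator | int | None, seed: int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(seed if rng is None else rng)


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return rr.astype(np.float64), cc.astype(np.float64)


def apply_shading(image: Image2D, amplitude: float, rng: np.random.Generator | int | None) -> Image2D:
    """Multiply the image by a smooth shading field in ``[1 - amplitude, 1]``.

    The field is white noise smoothed with a Gaussian of width one quarter of
    the image extent, min-max rescaled, so it only varies at spatial scales
    comparable to the field of view — the signature of surface-coil
    sensitivity shading.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ConfigurationError("amplitude must be in [0, 1)")
    if amplitude == 0.0:
        return Image2D(image.pixels.copy(), image.spacing, dict(image.meta))
    rng = _as_rng(rng, 0)
    field_ = shading_field(image.shape, amplitude, rng)
    return Image2D(image.pixels * field_, image.spacing, dict(image.meta))


def shading_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """The raw multiplicative field used by :func:`apply_shading`."""
    sigma = min(shape) / 4.0
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    lo, hi = raw.min(), raw.max()
    norm = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return 1.0 - amplitude * (1.0 - norm)


def _finalize_image(
    base: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Smooth edges, apply shading and Rician-approximated noise."""
    img = gaussian_filter(base, sigma=1.0, mode="nearest")
    if config.shading_amplitude > 0:
        img = img * shading_field(img.shape, config.shading_amplitude, rng)
    if config.noise_sd > 0:
        s = config.noise_sd
        n1 = rng.standard_normal(img.shape) * s
        n2 = rng.standard_normal(img.shape) * s
        img = np.sqrt((img + n1) ** 2 + n2**2)
    return img


def _jitter_and_clip(
    coords: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    out = coords + rng.normal(0.0, config.landmark_jitter_sd, coords.shape)
    rows, cols = config.image_size
    out[:, 0] = np.clip(out[:, 0], 1.0, rows - 2.0)
    out[:, 1] = np.clip(out[:, 1], 1.0, cols - 2.0)
    return out


def _background(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Plain tissue background with faint smooth texture."""
    base = np.full(config.image_size, 0.15)
    texture = gaussian_filter(rng.standard_normal(config.image_size), sigma=3.0, mode="nearest")
    return base + 0.03 * texture


def generate_long_axis(
    config: PhantomConfig, rng: np.random.Generator | int | None = None
) -> PhantomSample:
    """One long-axis frame: bullet-shaped ventricle, two valve points + apex.

    The silhouette half-width follows a quarter-ellipse profile from the base
    (full width) to the apex (zero width), so the apex-to-midbase distance of
    the emitted landmarks equals the sampled LV length exactly (before
    annotation jitter).
    """
    if config.view not in LONG_AXIS_VIEWS:
        raise ConfigurationError(f"generate_long_axis requires a long-axis view, got {config.view!r}")
    rng = _as_rng(rng, config.seed)
    sp = config.pixel_spacing
    length_mm = rng.uniform(*config.lv_length_range)
    radius_mm = rng.uniform(*config.lv_radius_range)
    wall_mm = rng.uniform(*config.wall_thickness_range)
    L, r, wall = length_mm / sp, radius_mm / sp, wall_mm / sp

    rows, cols = config.image_size
    theta = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([-math.sin(theta), math.cos(theta)])  # base -> apex
    v = np.array([-u[1], u[0]])

    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    bounding = math.hypot(L / 2.0, r) + wall + 2.0
    slack = max(0.0, min(rows, cols) / 2.0 - bounding - 2.0)
    center = center + rng.uniform(-1.0, 1.0, 2) * min(slack, 6.0)
    base_mid = center - u * (L / 2.0)

    rr, cc = _grid(config.image_size)
    drow, dcol = rr - base_mid[0], cc - base_mid[1]
    t = drow * u[0] + dcol * u[1]
    s = drow * v[0] + dcol * v[1]
    with np.errstate(invalid="ignore"):
        halfwidth = r * np.sqrt(np.clip(1.0 - (t / L) ** 2, 0.0, 1.0))
    cavity = (t >= 0.0) & (t <= L) & (np.abs(s) <= halfwidth)

    base = _background(config, rng)
    dist_out = distance_transform_edt(~cavity)
    base[cavity] = 1.0
    rim = (~cavity) & (dist_out <= wall)
    base[rim] = 0.45
    img = _finalize_image(base, config, rng)

    apex = base_mid + u * L
    valve_a = base_mid + v * r
    valve_b = base_mid - v * r
    coords = np.stack([valve_a, valve_b, apex])
    coords = _jitter_and_clip(coords, config, rng)
    landmarks = LandmarkSet(config.view, coords, np.ones(3, bool))
    params = {
        "lv_length_px": L,
        "lv_length_mm": length_mm,
        "radius_px": r,
        "wall_px": wall,
        "theta": theta,
        "base_mid": base_mid,
        "apex": apex,
        "valve_a": valve_a,
        "valve_b": valve_b,
    }
    return PhantomSample(Image2D(img, sp), landmarks, config.view, params)


def generate_short_axis(
    config: PhantomConfig, rng: np.random.Generator | int | None = None
) -> PhantomSample:
    """One short-axis frame: LV annulus with an RV crescent, or a landmark-free frame.

    The RV crescent hugs the epicardial boundary over an angular sector on
    the anatomically consistent (left/anterior) side of the LV; the insertion
    points sit at the sector ends on the epicardial circle.  With probability
    ``prob_no_landmark_frame`` the frame contains only background texture and
    all presence flags are false.
    """
    if config.view != "SAX":
        raise ConfigurationError(f"generate_short_axis requires view 'SAX', got {config.view!r}")
    rng = _as_rng(rng, config.seed)
    sp = config.pixel_spacing
    rows, cols = config.image_size

    if rng.uniform() < config.prob_no_landmark_frame:
        img = _finalize_image(_background(config, rng), config, rng)
        return PhantomSample(
            Image2D(img, sp), LandmarkSet.absent("SAX"), "SAX", {"landmark_free": True}
        )

    r_out = rng.uniform(*config.lv_radius_range) / sp
    wall = rng.uniform(*config.wall_thickness_range) / sp
    r_in = max(r_out - wall, 2.0)
    rv_thick = 0.55 * r_out

    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    bounding = r_out + rv_thick + 2.0
    slack = max(0.0, min(rows, cols) / 2.0 - bounding - 2.0)
    center = center + rng.uniform(-1.0, 1.0, 2) * min(slack, 6.0)

    # RV sits on the left/anterior side, as in routinely oriented SAX images.
    phi_c = math.radians(rng.uniform(150.0, 210.0))
    half_extent = math.radians(rng.uniform(40.0, 60.0))
    # Insertion points must be separated by at least the wall thickness.
    min_half = math.asin(min(1.0, wall / (2.0 * r_out))) * 1.2
    half_extent = max(half_extent, min_half)

    rr, cc = _grid(config.image_size)
    drow, dcol = rr - center[0], cc - center[1]
    dist = np.hypot(drow, dcol)
    # Angles measured counterclockwise from +col, row axis pointing down.
    ang = np.arctan2(-drow, dcol)
    dphi = np.angle(np.exp(1j * (ang - phi_c)))

    base = _background(config, rng)
    base[(dist > r_in) & (dist <= r_out)] = 0.4
    base[dist <= r_in] = 1.0
    if config.rv_crescent:
        rv = (dist > r_out) & (dist <= r_out + rv_thick) & (np.abs(dphi) <= half_extent)
        base[rv] = 0.9
    img = _finalize_image(base, config, rng)

    def on_circle(angle: float) -> np.ndarray:
        return center + r_out * np.array([-math.sin(angle), math.cos(angle)])

    a_rvi = on_circle(phi_c - half_extent)  # anterior (upper) junction
    p_rvi = on_circle(phi_c + half_extent)
    coords = np.stack([a_rvi, p_rvi, center])
    coords = _jitter_and_clip(coords, config, rng)
    landmarks = LandmarkSet("SAX", coords, np.ones(3, bool))
    params = {
        "center": center,
        "r_out_px": r_out,
        "r_in_px": r_in,
        "wall_px": wall,
        "phi_c": phi_c,
        "half_extent": half_extent,
        "a_rvi": a_rvi,
        "p_rvi": p_rvi,
    }
    return PhantomSample(Image2D(img, sp), landmarks, "SAX", params)


def generate_sample(
    config: PhantomConfig, rng: np.random.Generator | int | None = None
) -> PhantomSample:
    """Dispatch to the long- or short-axis generator based on ``config.view``."""
    if config.view == "SAX":
        return generate_short_axis(config, rng)
    return generate_long_axis(config, rng)


def generate_cine_series(
    config: PhantomConfig,
    n_phases: int = 30,
    contraction_fraction: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> list[PhantomSample]:
    """A contracting long-axis cine cycle with per-phase ground truth.

    The LV length of phase ``t`` (0-based) is
    ``L_ED * (1 - cf * (1 - cos(2*pi*t/n)) / 2)``: end-diastolic at phase 0,
    exactly ``(1 - cf) * L_ED`` at the mid-series end-systolic phase (even
    ``n``), and back near end-diastolic at the final phase.  Base position,
    orientation and width are held fixed; only the apex moves.
    """
    if n_phases < 2:
        raise ConfigurationError("n_phases must be >= 2")
    if not 0.0 < contraction_fraction < 1.0:
        raise ConfigurationError("contraction_fraction must be in (0, 1)")
    if config.view not in LONG_AXIS_VIEWS:
        raise ConfigurationError("cine series requires a long-axis view")
    rng = _as_rng(rng, config.seed)

    # Sample the end-diastolic geometry once, then replay it per phase with a
    # scaled length.  Reuse generate_long_axis for the drawing by pinning the
    # sampled parameters through a narrow config.
    sp = config.pixel_spacing
    length_ed = rng.uniform(*config.lv_length_range)
    radius = rng.uniform(*config.lv_radius_range)
    wall = rng.uniform(*config.wall_thickness_range)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    series: list[PhantomSample] = []
    frame_cfg_base = replace(
        config,
        lv_radius_range=(radius, radius),
        wall_thickness_range=(wall, wall),
        shading_amplitude=0.0,
    )
    shade = (
        shading_field(config.image_size, config.shading_amplitude, rng)
        if config.shading_amplitude > 0
        else None
    )
    for t in range(n_phases):
        frac = 1.0 - contraction_fraction * (1.0 - math.cos(2.0 * math.pi * t / n_phases)) / 2.0
        length_t = length_ed * frac
        frame_cfg = replace(frame_cfg_base, lv_length_range=(length_t, length_t))
        # A child generator replaying the fixed pose keeps noise independent
        # per frame while the anatomy stays registered across phases.
        sample = _long_axis_fixed_pose(frame_cfg, theta, shade, rng)
        sample.params["phase"] = t
        sample.params["lv_length_ed_mm"] = length_ed
        series.append(sample)
    return series


def _long_axis_fixed_pose(
    config: PhantomConfig,
    theta: float,
    shade: np.ndarray | None,
    rng: np.random.Generator,
) -> PhantomSample:
    """Draw a long-axis frame at a fixed orientation and centered base."""
    sp = config.pixel_spacing
    L = config.lv_length_range[0] / sp
    r = config.lv_radius_range[0] / sp
    wall = config.wall_thickness_range[0] / sp
    rows, cols = config.image_size
    u = np.array([-math.sin(theta), math.cos(theta)])
    v = np.array([-u[1], u[0]])
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    base_mid = center - u * (L / 2.0)

    rr, cc = _grid(config.image_size)
    drow, dcol = rr - base_mid[0], cc - base_mid[1]
    t = drow * u[0] + dcol * u[1]
    s = drow * v[0] + dcol * v[1]
    halfwidth = r * np.sqrt(np.clip(1.0 - (t / L) ** 2, 0.0, 1.0))
    cavity = (t >= 0.0) & (t <= L) & (np.abs(s) <= halfwidth)
    base = _background(config, rng)
    dist_out = distance_transform_edt(~cavity)
    base[cavity] = 1.0
    base[(~cavity) & (dist_out <= wall)] = 0.45
    img = gaussian_filter(base, sigma=1.0, mode="nearest")
    if shade is not None:
        img = img * shade
    if config.noise_sd > 0:
        s_n = config.noise_sd
        img = np.sqrt(
            (img + rng.standard_normal(img.shape) * s_n) ** 2
            + (rng.standard_normal(img.shape) * s_n) ** 2
        )

    apex = base_mid + u * L
    coords = np.stack([base_mid + v * r, base_mid - v * r, apex])
    coords = _jitter_and_clip(coords, config, rng)
    landmarks = LandmarkSet(config.view, coords, np.ones(3, bool))
    params = {
        "lv_length_px": L,
        "lv_length_mm": L * sp,
        "radius_px": r,
        "theta": theta,
        "base_mid": base_mid,
        "apex": apex,
    }
    return PhantomSample(Image2D(img, sp), landmarks, config.view, params)


def invert_contrast(sample: PhantomSample) -> PhantomSample:
    """The same anatomy with inverted intensities (dark blood pool).

    Emulates switching to an image contrast where the structures that were
    bright become dark, the analogue of moving from cine to late-enhancement
    appearance, as a target domain for transfer learning.
    """
    px = sample.image.pixels
    inv = px.max() + px.min() - px
    img = Image2D(inv, sample.image.spacing, dict(sample.image.meta))
    return PhantomSample(img, sample.landmarks.copy(), sample.view, dict(sample.params))


def generate_dataset(
    config: PhantomConfig,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
    samples_per_patient: int = 1,
) -> list[PhantomSample]:
    """A list of independent samples with synthetic patient/sample ids in meta."""
    rng = _as_rng(rng, config.seed)
    out = []
    for i in range(n_samples):
        s = generate_sample(config, rng)
        s.image.meta["sample_id"] = f"s{i:05d}"
        s.image.meta["patient_id"] = f"p{i // max(1, samples_per_patient):05d}"
        s.image.meta["view"] = config.view
        out.append(s)
    return out
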