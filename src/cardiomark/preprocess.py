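"""Bring images onto the detector grid and correct intensity shading.

The detector operates on a fixed grid (default 400x400 px at 1 mm): inputs
are first resampled to the target spacing with bilinear interpolation, then
center-padded or center-cropped.  Both steps return a companion
:class:`CoordinateMap` so landmark annotations can be carried through the
same geometry exactly.

Surface-coil shading is handled by estimating a slowly varying multiplicative
bias field (a robust low-order polynomial surface fit to the log
intensities, normalized to peak 1) and dividing it out while preserving the
image mean.  At training time a sample
is fed either as acquired or shading-corrected (a coin flip with
``p_use_original``), followed by random rotation / scale / translation /
gamma applied jointly to image and landmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ConfigurationError, Image2D, LandmarkSet


@dataclass
class CoordinateMap:
    """Axis-aligned affine map ``new = coords * scale + offset`` on (row, col)."""

    scale: tuple[float, float] = (1.0, 1.0)
    offset: tuple[float, float] = (0.0, 0.0)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=np.float64)
        return c * np.asarray(self.scale) + np.asarray(self.offset)

    def compose(self, first: "CoordinateMap") -> "CoordinateMap":
        """The map equivalent to applying ``first`` then ``self``."""
        s = (self.scale[0] * first.scale[0], self.scale[1] * first.scale[1])
        o = (
            self.scale[0] * first.offset[0] + self.offset[0],
            self.scale[1] * first.offset[1] + self.offset[1],
        )
        return CoordinateMap(s, o)

    def inverse(self) -> "CoordinateMap":
        s = (1.0 / self.scale[0], 1.0 / self.scale[1])
        return CoordinateMap(s, (-self.offset[0] * s[0], -self.offset[1] * s[1]))

    def apply_landmarks(self, landmarks: LandmarkSet, shape: tuple[int, int]) -> LandmarkSet:
        """Transform a landmark set, marking landmarks mapped out of ``shape`` absent."""
        out = landmarks.copy()
        out.coords = self.apply(out.coords)
        for k in range(out.n_landmarks):
            if out.present[k]:
                r, c = out.coords[k]
                if not (0.0 <= r <= shape[0] - 1 and 0.0 <= c <= shape[1] - 1):
                    out.present[k] = False
                    out.coords[k] = np.nan
        return out


@dataclass
class PreprocessConfig:
    """Grid, shading-correction and augmentation parameters.

    Augmentation uses label-preserving transforms only: mirror flips are
    deliberately excluded because they invert anterior/posterior landmark
    semantics.
    """

    target_spacing: float = 1.0
    target_size: tuple[int, int] = (400, 400)
    p_use_original: float = 0.5
    bias_degree: int = 3
    intensity_floor: float = 1e-3
    rotation_deg: float = 30.0
    scale_frac: float = 0.1
    translation_px: float = 20.0
    gamma_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ConfigurationError("target_spacing must be positive")
        if self.target_size[0] % 2 or self.target_size[1] % 2:
            raise ConfigurationError("target_size must be even in both dimensions")
        if not 0.0 <= self.p_use_original <= 1.0:
            raise ConfigurationError("p_use_original must be in [0, 1]")
        if self.intensity_floor <= 0:
            raise ConfigurationError("intensity_floor must be positive")


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def resample_to_spacing(
    image: Image2D, target_spacing: float
) -> tuple[Image2D, CoordinateMap]:
    """Resample to an isotropic target spacing with bilinear interpolation.

    The output size is ``round(input_size * input_spacing / target_spacing)``
    (round-half-to-even); output pixel ``(i, j)`` samples the input at
    ``(i / z_r, j / z_c)`` where ``z`` is the realized size ratio, and the
    companion map scales landmark coordinates by the same ratio.
    """
    if target_spacing <= 0:
        raise ConfigurationError("target_spacing must be positive")
    in_rows, in_cols = image.shape
    factor = image.spacing / target_spacing
    out_rows = max(1, _round_half_even(in_rows * factor))
    out_cols = max(1, _round_half_even(in_cols * factor))
    if (out_rows, out_cols) == (in_rows, in_cols) and math.isclose(factor, 1.0):
        return Image2D(image.pixels.copy(), target_spacing, dict(image.meta)), CoordinateMap()
    z_r, z_c = out_rows / in_rows, out_cols / in_cols
    rr = np.arange(out_rows, dtype=np.float64)[:, None] / z_r
    cc = np.arange(out_cols, dtype=np.float64)[None, :] / z_c
    coords = np.broadcast_arrays(rr, cc)
    out = ndimage.map_coordinates(
        image.pixels, np.stack(coords), order=1, mode="nearest"
    )
    return (
        Image2D(out, target_spacing, dict(image.meta)),
        CoordinateMap((z_r, z_c), (0.0, 0.0)),
    )


def pad_or_crop(
    image: Image2D, target_size: tuple[int, int]
) -> tuple[Image2D, CoordinateMap]:
    """Center the content on a fixed grid, zero-padding or cropping per axis.

    Padding splits equally (extra pixel on the high-index side when odd);
    cropping removes equal margins (extra pixel removed from the high-index
    side when odd).
    """
    out = np.zeros(target_size, dtype=image.pixels.dtype)
    offsets = []
    src_slices, dst_slices = [], []
    for axis in range(2):
        n_in, n_out = image.shape[axis], target_size[axis]
        if n_in <= n_out:
            low = (n_out - n_in) // 2
            src_slices.append(slice(0, n_in))
            dst_slices.append(slice(low, low + n_in))
            offsets.append(float(low))
        else:
            low = (n_in - n_out) // 2
            src_slices.append(slice(low, low + n_out))
            dst_slices.append(slice(0, n_out))
            offsets.append(-float(low))
    out[tuple(dst_slices)] = image.pixels[tuple(src_slices)]
    return (
        Image2D(out, image.spacing, dict(image.meta)),
        CoordinateMap((1.0, 1.0), (offsets[0], offsets[1])),
    )


def to_detector_grid(
    image: Image2D,
    config: PreprocessConfig,
) -> tuple[Image2D, CoordinateMap]:
    """Resample then pad/crop; the returned map composes both steps."""
    resampled, m1 = resample_to_spacing(image, config.target_spacing)
    gridded, m2 = pad_or_crop(resampled, config.target_size)
    return gridded, m2.compose(m1)


def estimate_bias_field(
    image: Image2D | np.ndarray,
    degree: int = 3,
    intensity_floor: float = 1e-3,
    n_irls: int = 4,
    robust_c: float = 0.4,
) -> np.ndarray:
    """Estimate a slowly varying multiplicative shading field.

    A polynomial surface of total ``degree`` is fit to the log intensities
    by iteratively reweighted least squares, downweighting pixels that sit
    far *above* the surface (bright anatomy is an outlier to the shading,
    not part of it).  The exponentiated surface is normalized so its
    maximum is 1 and floored at ``intensity_floor``.  An all-zero image
    yields a flat field of ones.

    Because the fit is a projection in log space, dividing the field out
    and re-estimating yields a flat field: the correction is idempotent.
    """
    pixels = image.pixels if isinstance(image, Image2D) else np.asarray(image, float)
    if not np.any(pixels > 0):
        return np.ones_like(pixels)
    rows, cols = pixels.shape
    log_i = np.log(np.maximum(pixels, intensity_floor * pixels.max()))
    yy, xx = np.meshgrid(
        np.linspace(-1.0, 1.0, rows), np.linspace(-1.0, 1.0, cols), indexing="ij"
    )
    basis = [
        (yy**i * xx**j).ravel()
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    A = np.stack(basis, axis=1)
    b = log_i.ravel()
    w = np.ones_like(b)
    coef = np.zeros(A.shape[1])
    for _ in range(max(1, n_irls)):
        coef, *_ = np.linalg.lstsq(A * w[:, None], b * w, rcond=None)
        resid = b - A @ coef
        w = 1.0 / (1.0 + (np.maximum(resid, 0.0) / robust_c) ** 2)
    field = np.exp((A @ coef).reshape(rows, cols))
    field = field / field.max()
    return np.maximum(field, intensity_floor)


def correct_inhomogeneity(image: Image2D, field: np.ndarray) -> Image2D:
    """Divide out a bias field, rescaling to preserve the input mean."""
    field = np.asarray(field, dtype=np.float64)
    if field.shape != image.shape:
        raise ValueError(f"field shape {field.shape} != image shape {image.shape}")
    if np.any(field <= 0):
        raise ValueError("bias field must be strictly positive")
    out = image.pixels / field
    m = out.mean()
    if m > 0:
        out = out * (image.pixels.mean() / m)
    return Image2D(out, image.spacing, dict(image.meta))


def normalize_intensity(pixels: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Scale to [0, 1] by the 1st-99th percentile window (clipped)."""
    lo, hi = np.percentile(pixels, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(pixels, dtype=np.float64)
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)


def _rotation_scale_matrix(theta_rad: float, scale: float) -> np.ndarray:
    # Positive angle rotates a point at the top of the image toward the
    # right edge (row axis points down); 90 deg maps (dr, dc) -> (dc, -dr).
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    return scale * np.array([[c, s], [-s, c]])


def affine_about_center(
    image: Image2D,
    landmarks: LandmarkSet | None,
    theta_deg: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
) -> tuple[Image2D, LandmarkSet | None]:
    """Rotate/scale about the image center and translate, jointly with landmarks.

    Landmarks carried out of bounds are marked absent.
    """
    rows, cols = image.shape
    if theta_deg == 0.0 and scale == 1.0 and translation == (0.0, 0.0):
        return Image2D(image.pixels.copy(), image.spacing, dict(image.meta)), (
            landmarks.copy() if landmarks is not None else None
        )
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    t = np.asarray(translation, dtype=np.float64)
    M = _rotation_scale_matrix(math.radians(theta_deg), scale)
    Minv = np.linalg.inv(M)
    # ndimage pulls: output[o] = input[Minv @ o + offset]
    offset = center - Minv @ (center + t)
    warped = ndimage.affine_transform(
        image.pixels, Minv, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_img = Image2D(warped, image.spacing, dict(image.meta))
    out_lm = None
    if landmarks is not None:
        out_lm = landmarks.copy()
        rel = out_lm.coords - center
        out_lm.coords = rel @ M.T + center + t
        for k in range(out_lm.n_landmarks):
            if out_lm.present[k]:
                r, c = out_lm.coords[k]
                if not (0.0 <= r <= rows - 1 and 0.0 <= c <= cols - 1):
                    out_lm.present[k] = False
                    out_lm.coords[k] = np.nan
    return out_img, out_lm


def augment(
    image: Image2D,
    landmarks: LandmarkSet,
    config: PreprocessConfig,
    rng: np.random.Generator,
) -> tuple[Image2D, LandmarkSet]:
    """One training-time augmentation draw.

    With probability ``p_use_original`` the image is used as acquired,
    otherwise shading-corrected; then a random rotation, isotropic scale,
    translation and intensity gamma are applied jointly to the image and the
    landmark coordinates.
    """
    img = image
    if rng.uniform() >= config.p_use_original:
        field = estimate_bias_field(img, config.bias_degree, config.intensity_floor)
        img = correct_inhomogeneity(img, field)
    theta = rng.uniform(-config.rotation_deg, config.rotation_deg)
    scale = 1.0 + rng.uniform(-config.scale_frac, config.scale_frac)
    trans = tuple(rng.uniform(-config.translation_px, config.translation_px, 2))
    img, lms = affine_about_center(img, landmarks, theta, scale, trans)
    gamma = rng.uniform(*config.gamma_range)
    if gamma != 1.0:
        lo, hi = img.pixels.min(), img.pixels.max()
        if hi > lo:
            norm = (img.pixels - lo) / (hi - lo)
            img = Image2D(lo + (hi - lo) * norm**gamma, img.spacing, dict(img.meta))
    assert lms is not None
    return img, lms
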