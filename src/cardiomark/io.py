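"""Readers and writers: landmark CSV tables, phantom datasets, images.

The landmark table is the exchange format across the package: one row per
(sample, role) with columns ``sample_id, view, landmark_role, row, col,
present`` (detection tables add ``peak_prob``).  Absent landmarks keep empty
coordinates.

Image loading dispatches on extension: DICOM via pydicom, NIfTI via nibabel,
plain images via imageio, NumPy arrays via ``.npy``.  Pixel spacing is read
from metadata when the container carries it, otherwise it must be supplied.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DetectionResult, Image2D, LandmarkSet, VIEW_ROLES
from .phantom import PhantomConfig, PhantomSample

LANDMARK_COLUMNS = ["sample_id", "view", "landmark_role", "row", "col", "present"]


def landmarks_to_frame(
    items: Sequence[tuple[str, LandmarkSet | DetectionResult]]
) -> pd.DataFrame:
    """Landmark sets (or detections) as a tidy table."""
    rows = []
    for sample_id, lm in items:
        det = lm if isinstance(lm, DetectionResult) else None
        lms = det.to_landmark_set() if det is not None else lm
        for k, role in enumerate(lms.roles):
            row = {
                "sample_id": sample_id,
                "view": lms.view,
                "landmark_role": role,
                "row": lms.coords[k, 0] if lms.present[k] else np.nan,
                "col": lms.coords[k, 1] if lms.present[k] else np.nan,
                "present": bool(lms.present[k]),
            }
            if det is not None:
                row["peak_prob"] = float(det.peak_probs[k])
            rows.append(row)
    return pd.DataFrame(rows)


def write_landmark_csv(
    items: Sequence[tuple[str, LandmarkSet | DetectionResult]], path
) -> None:
    landmarks_to_frame(items).to_csv(path, index=False, float_format="%.6f")


def read_landmark_csv(path) -> dict[str, LandmarkSet]:
    """Read a landmark table back into per-sample landmark sets."""
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV is missing columns: {sorted(missing)}")
    out: dict[str, LandmarkSet] = {}
    for sample_id, group in df.groupby("sample_id", sort=False):
        view = group["view"].iloc[0]
        roles = VIEW_ROLES[view]
        coords = np.full((len(roles), 2), np.nan)
        present = np.zeros(len(roles), bool)
        by_role = group.set_index("landmark_role")
        for k, role in enumerate(roles):
            if role not in by_role.index:
                continue
            rec = by_role.loc[role]
            if bool(rec["present"]):
                present[k] = True
                coords[k] = (float(rec["row"]), float(rec["col"]))
        out[str(sample_id)] = LandmarkSet(view, coords, present)
    return out


# ---------------------------------------------------------------------------
# phantom dataset round trip


def save_dataset(samples: Sequence[PhantomSample], out_dir, config: PhantomConfig | None = None,
                 image_format: str = "npy") -> None:
    """Write images, the landmark table, and a manifest with config + seed."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    items = []
    for i, s in enumerate(samples):
        sid = s.image.meta.get("sample_id", f"s{i:05d}")
        if image_format == "npy":
            np.save(out / "images" / f"{sid}.npy", s.image.pixels)
        elif image_format == "png":
            import imageio.v3 as iio

            arr = s.image.pixels
            lo, hi = arr.min(), arr.max()
            scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
            iio.imwrite(out / "images" / f"{sid}.png", (scaled * 65535).astype(np.uint16))
        else:
            raise ValueError(f"unknown image_format {image_format!r}")
        items.append((sid, s.landmarks))
    write_landmark_csv(items, out / "landmarks.csv")
    manifest = {
        "n_samples": len(samples),
        "image_format": image_format,
        "spacing": samples[0].image.spacing if samples else 1.0,
        "views": sorted({s.view for s in samples}),
        "config": _config_to_dict(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_to_dict(config: PhantomConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d


def load_manifest(dataset_dir) -> dict:
    manifest = json.loads((Path(dataset_dir) / "manifest.json").read_text())
    return manifest


def load_config_from_manifest(manifest: dict) -> PhantomConfig | None:
    if manifest.get("config") is None:
        return None
    cfg = dict(manifest["config"])
    for key in ("image_size", "lv_length_range", "lv_radius_range", "wall_thickness_range"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return PhantomConfig(**cfg)


def load_dataset(dataset_dir) -> list[PhantomSample]:
    """Round-trip reader for :func:`save_dataset` output."""
    root = Path(dataset_dir)
    manifest = load_manifest(root)
    landmark_sets = read_landmark_csv(root / "landmarks.csv")
    spacing = float(manifest.get("spacing", 1.0))
    fmt = manifest.get("image_format", "npy")
    samples = []
    for sid, lms in landmark_sets.items():
        if fmt == "npy":
            pixels = np.load(root / "images" / f"{sid}.npy")
        else:
            import imageio.v3 as iio

            pixels = iio.imread(root / "images" / f"{sid}.png").astype(np.float64) / 65535.0
        img = Image2D(pixels, spacing, {"sample_id": sid, "view": lms.view})
        samples.append(PhantomSample(img, lms, lms.view))
    return samples


# ---------------------------------------------------------------------------
# medical-image containers


def load_image(path, spacing: float | None = None, view: str | None = None) -> Image2D:
    """Load a 2D grayscale image from common containers.

    Spacing is taken from DICOM ``PixelSpacing`` / NIfTI zooms when present;
    for plain images and arrays it must be provided (or defaults to 1 mm).
    """
    p = Path(path)
    suffix = "".join(p.suffixes).lower()
    meta: dict = {"source": str(p)}
    if view:
        meta["view"] = view
    if suffix.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(p)
        pixels = ds.pixel_array.astype(np.float64)
        if spacing is None and getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
    elif ".nii" in suffix:
        import nibabel as nib

        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{p}: expected a 2D volume, got shape {data.shape}")
        pixels = data
        if spacing is None:
            zooms = img.header.get_zooms()
            spacing = float(zooms[0])
    elif suffix.endswith(".npy"):
        pixels = np.load(p).astype(np.float64)
    else:
        import imageio.v3 as iio

        arr = iio.imread(p)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        pixels = arr.astype(np.float64)
    if spacing is None:
        spacing = 1.0
    return Image2D(pixels, spacing, meta)
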