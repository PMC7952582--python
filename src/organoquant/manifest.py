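"""Manifest and image I/O.

The manifest is a CSV mapping every image to its experimental cell:
``image_id, path, arm, dose, treated, day, seed``.  Images are 8-bit
greyscale PNG/TIFF; truth and predicted label masks are written as 16-bit
single-channel images.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "read_image",
    "write_image",
    "write_label_mask",
    "read_label_mask",
    "write_features",
    "read_features",
]

MANIFEST_COLUMNS = ["image_id", "path", "arm", "dose", "treated", "day", "seed"]

_FEATURE_COLUMNS = [
    "image_id",
    "label",
    "area_px",
    "centroid_row",
    "centroid_col",
    "bbox_row_min",
    "bbox_col_min",
    "bbox_row_max",
    "bbox_col_max",
    "mean_intensity",
]


def write_manifest(manifest: pd.DataFrame, path: "str | Path") -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    manifest.to_csv(path, index=False)


def read_manifest(path: "str | Path", check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Checks required columns, image-id uniqueness and (optionally) that
    every non-empty image path resolves relative to the manifest file.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_id": str, "path": str, "arm": str, "dose": str})
    df["path"] = df["path"].fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    dup = df["image_id"][df["image_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"manifest {path} has duplicate image_id: {sorted(set(dup))}")
    df["treated"] = df["treated"].astype(bool)
    if check_paths:
        for _, row in df.iterrows():
            if row["path"]:
                p = Path(row["path"])
                if not p.is_absolute():
                    p = path.parent / p
                if not p.exists():
                    raise FileNotFoundError(
                        f"manifest {path}: image {row['image_id']} path not found: {p}"
                    )
    return df


def resolve_path(manifest_path: "str | Path", image_path: str) -> Path:
    p = Path(image_path)
    if not p.is_absolute():
        p = Path(manifest_path).parent / p
    return p


def read_image(path: "str | Path") -> np.ndarray:
    """Read a PNG/TIFF image (grey or RGB, 8- or 16-bit)."""
    return np.asarray(iio.imread(Path(path)))


def write_image(image: np.ndarray, path: "str | Path") -> None:
    """Write an 8-bit greyscale image as PNG or TIFF."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_label_mask(labels: np.ndarray, path: "str | Path") -> None:
    """Write a label map as 16-bit single-channel PNG/TIFF."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map does not fit a 16-bit image")
    iio.imwrite(Path(path), lab.astype(np.uint16))


def read_label_mask(path: "str | Path") -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.int32)


def write_features(features: pd.DataFrame, path: "str | Path") -> None:
    missing = [c for c in _FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"features table is missing columns: {missing}")
    features.to_csv(path, index=False)


def read_features(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"features table {path} is missing columns: {missing}")
    return df


def features_frame(image_id: str, objects) -> pd.DataFrame:
    """Per-object features of one image as a tidy DataFrame."""
    rows = [
        {
            "image_id": image_id,
            "label": o.label,
            "area_px": o.area_px,
            "centroid_row": o.centroid[0],
            "centroid_col": o.centroid[1],
            "bbox_row_min": o.bbox[0],
            "bbox_col_min": o.bbox[1],
            "bbox_row_max": o.bbox[2],
            "bbox_col_max": o.bbox[3],
            "mean_intensity": o.mean_intensity,
        }
        for o in objects
    ]
    return pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
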