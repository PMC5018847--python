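"""File I/O: photographs, clutch masks, metadata tables, audit exports.

Photographs are 3-channel TIFF or PNG, 8- or 16-bit, already
color-managed; the per-nest metadata CSV supplies each image's colorspace
tag and pixel scale.  Masks are single-channel PNGs (nonzero = clutch).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .color import RgbScene
from .regions import ClutchMask, RegionSet

#: Columns the nest metadata table must provide.
METADATA_COLUMNS = ["nest_id", "species", "image", "mask", "pixels_per_cm", "colorspace"]


def read_scene(path, colorspace_tag: str, pixels_per_cm: float) -> RgbScene:
    """Load a calibrated photograph as an RgbScene with components in [0,1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        pixels = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(float)
    else:
        raise ValueError(f"{path}: unsupported image dtype {arr.dtype}")
    return RgbScene(pixels=pixels, colorspace_tag=colorspace_tag, pixels_per_cm=pixels_per_cm)


def write_scene(path, scene: RgbScene, bitdepth: int = 8) -> None:
    """Write an RgbScene as PNG/TIFF at the requested bit depth."""
    if bitdepth == 8:
        arr = np.round(scene.pixels * 255).astype(np.uint8)
    elif bitdepth == 16:
        arr = np.round(scene.pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(Path(path), arr)


def read_mask(path) -> ClutchMask:
    """Load a clutch mask PNG (nonzero pixels mark the clutch)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ClutchMask(mask=arr > 0)


def write_mask(path, mask: ClutchMask) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8)) * 255)


def write_region_labels(path, regions: RegionSet) -> None:
    """Audit export: 0 = background, 1 = contour band, 2 = internal."""
    iio.imwrite(Path(path), regions.to_labels())


def write_edge_png(path, edges) -> None:
    """Accepts a boolean edge array or an EdgeMap."""
    arr = getattr(edges, "edges", edges)
    iio.imwrite(Path(path), (np.asarray(arr, dtype=bool).astype(np.uint8)) * 255)


def read_metadata(path) -> pd.DataFrame:
    """Load and schema-check the nest metadata CSV."""
    df = pd.read_csv(Path(path))
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns {missing}")
    dup = df["nest_id"][df["nest_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate nest_id values: {sorted(dup.unique())}")
    return df
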