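"""Reading and writing of images, masks and run artifacts.

Images are 8-bit single-channel PNG or TIFF; RGB input is rejected rather
than silently converted, because color weighting would change the gray
levels being clustered.  Masks are written as 0/255 PNG, label maps as a
scaled PNG (index x 42 for visibility) plus a lossless integer TIFF, and
traces/centers as CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_gray",
    "read_mask",
    "write_mask",
    "write_labels",
    "write_trace",
    "write_centers",
]


def read_gray(path) -> np.ndarray:
    """Load a 2D grayscale image as float intensities in [0, 255]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: expected a single-channel grayscale image, got shape {arr.shape}; "
            "convert RGB input to grayscale first"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got {arr.ndim} dimensions")
    return arr.astype(float)


def read_mask(path) -> np.ndarray:
    """Load a binary mask (any nonzero pixel counts as foreground)."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D mask, got shape {arr.shape}")
    return arr > 0


def write_mask(path, mask) -> None:
    """Write a boolean mask as 0/255 8-bit PNG (or TIFF by extension)."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out)


def write_labels(path_png, label_map, path_tiff=None) -> None:
    """Write a label map: scaled 8-bit PNG, optionally exact uint16 TIFF."""
    labels = np.asarray(label_map)
    iio.imwrite(path_png, np.clip(labels * 42, 0, 255).astype(np.uint8))
    if path_tiff is not None:
        iio.imwrite(path_tiff, labels.astype(np.uint16))


def write_trace(path, trace) -> None:
    """Per-generation best-cost trace as CSV (generation, best_cost)."""
    trace = np.asarray(trace, dtype=float)
    pd.DataFrame(
        {"generation": np.arange(trace.size), "best_cost": trace}
    ).to_csv(path, index=False)


def write_centers(path, centers) -> None:
    centers = np.asarray(centers, dtype=float)
    pd.DataFrame(
        {"cluster": np.arange(centers.size), "center": centers}
    ).to_csv(path, index=False)


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
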