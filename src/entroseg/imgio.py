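"""Image and table I/O.

Reads TIFF/PNG/JPEG rasters into 8-bit RGB arrays (16-bit inputs are
rescaled with a warning), writes binary masks as single-channel PNGs
with the pipeline's foreground-is-0 coding, and round-trips score
tables as plain CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["read_rgb", "read_mask", "write_mask", "write_scores", "read_scores"]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an image file as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated across channels; an alpha channel is
    dropped; 16-bit data are rescaled to 8 bits with a warning.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"{path}: expected an RGB(A) or grayscale raster, got shape {arr.shape}")
    arr = arr[..., :3]
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: rescaling 16-bit data to 8 bits", stacklevel=2)
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(f"{path}: cannot interpret dtype {arr.dtype} as 8-bit RGB")
        arr = arr.astype(np.uint8)
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary segmentation mask (foreground = 0, background = 255)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 255))):
        raise ValueError(f"{path}: mask must contain only values 0 and 255")
    return arr.astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel PNG."""
    arr = np.asarray(mask)
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 255))):
        raise ValueError("mask must contain only values 0 and 255")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def write_scores(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
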