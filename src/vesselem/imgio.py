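"""Image reading/writing helpers (PNG, TIFF, PPM, GIF)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InvalidInputError

__all__ = ["read_image", "read_mask", "write_image", "write_mask", "write_float_tiff"]


def read_image(path) -> np.ndarray:
    """Read an image as a float array (grayscale 2-D or colour H x W x C)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 4:  # animated formats (GIF): first frame
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr.astype(float)


def read_mask(path) -> np.ndarray:
    """Read a binary mask; any channel above zero counts as foreground."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return arr > 0


def write_image(path, image: np.ndarray) -> None:
    """Write an image, rounding floats to uint8."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), image)


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def write_float_tiff(path, field: np.ndarray) -> None:
    """Write a scalar field (e.g. a bias field) as 32-bit float TIFF."""
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 2:
        raise InvalidInputError("expected a 2-D scalar field")
    tifffile.imwrite(Path(path), field)
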