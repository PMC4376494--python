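"""Adaptive histogram equalisation, binary pruning, and the distance map.

The equalisation is a windowed rank transform: each output pixel is
``255 * (c / h^2) ** r`` where ``c`` counts the pixels in the h-by-h window
that are strictly darker than the centre.  It therefore depends only on the
strict ordering of intensities inside each window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening as _gray_opening

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "EnhancementConfig",
    "DistanceMap",
    "adaptive_hist_eq",
    "binarize_and_open",
    "distance_map",
]

logger = logging.getLogger(__name__)

#: images with more distinct intensities than this are binned before ranking
MAX_EXACT_LEVELS = 1024


@dataclass
class EnhancementConfig:
    r: float = 3.0
    h: int = 81
    open_radius: int = 1
    binarize_quantile: float = 0.80

    def __post_init__(self) -> None:
        if self.h < 3 or self.h % 2 == 0:
            raise ConfigurationError("window width h must be odd and >= 3")
        if self.r < 1:
            raise ConfigurationError("contrast exponent r must be >= 1")
        if self.open_radius < 0:
            raise ConfigurationError("open_radius must be >= 0")
        if not 0.0 < self.binarize_quantile < 1.0:
            raise ConfigurationError("binarize_quantile must be in (0, 1)")


@dataclass
class DistanceMap:
    """Euclidean distance of each foreground pixel to the nearest background pixel."""

    values: np.ndarray


def _box_count(indicator: np.ndarray, h: int) -> np.ndarray:
    """Exact integer h-by-h box sums of ``indicator`` (valid region only)."""
    ii = np.zeros((indicator.shape[0] + 1, indicator.shape[1] + 1), dtype=np.int64)
    np.cumsum(indicator, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    return (ii[h:, h:] - ii[:-h, h:] - ii[h:, :-h] + ii[:-h, :-h])


def windowed_rank_counts(image: np.ndarray, h: int) -> np.ndarray:
    """Count, per pixel, the window pixels strictly darker than the centre.

    Uses reflection padding so every pixel sees a full h-by-h window.  Counts
    are exact integers; images with more than ``MAX_EXACT_LEVELS`` distinct
    values are first quantised to 256 equal-width intensity bins.
    """
    image = np.asarray(image)
    pad = h // 2
    padded = np.pad(image, pad, mode="reflect")
    levels, inverse = np.unique(padded, return_inverse=True)
    if levels.size > MAX_EXACT_LEVELS:
        lo, hi = float(levels[0]), float(levels[-1])
        quantised = np.minimum((padded.astype(float) - lo) * (256.0 / (hi - lo)), 255.0)
        idx = quantised.astype(np.int64)
        n_levels = 256
    else:
        idx = inverse.reshape(padded.shape)
        n_levels = levels.size

    counts = np.zeros(image.shape, dtype=np.int64)
    core = idx[pad:idx.shape[0] - pad, pad:idx.shape[1] - pad]
    for li in range(n_levels):
        present = core == li
        if present.any():
            counts[present] = _box_count((idx < li).astype(np.int64), h)[present]
    return counts


def adaptive_hist_eq(image: np.ndarray, config: EnhancementConfig) -> np.ndarray:
    """Windowed rank-based adaptive histogram equalisation.

    Output pixel = ``255 * (c(q) / h**2) ** r`` with ``c(q)`` the number of
    strictly darker pixels in the h-by-h window centred at q (centre included
    in the window; borders reflection-padded).

    Returns a float image in [0, 255].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidInputError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise InvalidInputError("image contains non-finite values")
    counts = windowed_rank_counts(image, config.h)
    return 255.0 * (counts / float(config.h * config.h)) ** config.r


def binarize_and_open(enhanced: np.ndarray, config: EnhancementConfig,
                      fov: np.ndarray | None = None) -> np.ndarray:
    """Threshold the enhanced image at a quantile, then binary-open.

    The quantile is taken over FOV pixels when a mask is supplied, and the
    output is restricted to the FOV.  Opening (erosion then dilation) with a
    disk of ``open_radius`` never adds foreground pixels.
    """
    enhanced = np.asarray(enhanced, dtype=float)
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        sample = enhanced[fov]
    else:
        sample = enhanced.ravel()
    threshold = np.quantile(sample, config.binarize_quantile)
    mask = enhanced > threshold
    if fov is not None:
        mask &= fov
    if config.open_radius > 0:
        mask = _gray_opening(mask, disk(config.open_radius))
    return mask


def distance_map(mask: np.ndarray) -> DistanceMap:
    """Euclidean distance transform of a binary mask.

    Foreground pixels get their distance to the nearest background pixel;
    background pixels are exactly 0.  An all-foreground mask falls back to the
    distance to the image border (logged as a warning).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.all() and mask.size:
        logger.warning("distance_map: mask has no background; "
                       "using distance to the image border")
        padded = np.pad(mask, 1, mode="constant", constant_values=False)
        values = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        return DistanceMap(values=values)
    return DistanceMap(values=ndimage.distance_transform_edt(mask))
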