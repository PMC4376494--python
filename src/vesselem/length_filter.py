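"""Connected-component size filtering of the EM output mask.

Components are labelled with 8-connectivity; groups smaller than a pixel-count
threshold are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _sk_label

from .errors import InvalidInputError

__all__ = ["LabeledMask", "label_components", "filter_by_size", "apply_length_filter"]


@dataclass
class LabeledMask:
    """8-connected component labelling of a binary mask.

    ``labels`` uses 0 for background and consecutive integers 1..n_components
    for foreground objects; ``component_sizes`` maps each label to its pixel
    count.
    """

    labels: np.ndarray
    n_components: int
    component_sizes: dict


def label_components(mask: np.ndarray) -> LabeledMask:
    """Label the 8-connected components of a binary mask."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidInputError("mask must be 2-D")
    mask = mask.astype(bool)
    labels, n = _sk_label(mask, connectivity=2, return_num=True)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    sizes = {lab: int(counts[lab]) for lab in range(1, n + 1)}
    return LabeledMask(labels=labels, n_components=int(n), component_sizes=sizes)


def filter_by_size(labeled: LabeledMask, min_size: int) -> np.ndarray:
    """Keep only components with at least ``min_size`` pixels.

    Components of size exactly ``min_size`` survive; smaller ones are dropped.
    """
    if min_size < 0:
        raise InvalidInputError("min_size must be >= 0")
    if labeled.n_components == 0:
        return np.zeros(labeled.labels.shape, dtype=bool)
    keep = np.zeros(labeled.n_components + 1, dtype=bool)
    for lab, size in labeled.component_sizes.items():
        keep[lab] = size >= min_size
    keep[0] = False
    return keep[labeled.labels]


def apply_length_filter(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Label then size-filter in one call."""
    return filter_by_size(label_components(mask), min_size)
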