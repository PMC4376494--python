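"""Segmentation evaluation: TPR / FPR / accuracy and FOV mask construction."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from skimage.measure import label as _sk_label

from .errors import InvalidInputError

__all__ = ["SegmentationMetrics", "compute_metrics", "fov_mask_from_rgb"]

#: default per-channel FOV threshold (8-bit scale)
DEFAULT_FOV_THRESHOLDS = (40.0, 40.0, 40.0)


@dataclass
class SegmentationMetrics:
    """Pixel-level confusion counts and rates, evaluated inside the FOV.

    ``accuracy`` is FOV-restricted; ``accuracy_whole_image`` covers every
    pixel of the masks regardless of the FOV.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    accuracy: float
    accuracy_whole_image: float

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_ratio(num: int, den: int) -> float:
    return float(num) / float(den) if den > 0 else 0.0


def compute_metrics(pred: np.ndarray, truth: np.ndarray,
                    fov: np.ndarray | None = None) -> SegmentationMetrics:
    """Confusion counts of a predicted vessel mask against ground truth.

    TPR = tp / (tp + fn), FPR = fp / (fp + tn) and accuracy are computed over
    FOV pixels only; whole-image accuracy over all pixels is also reported.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise InvalidInputError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    if fov is None:
        fov = np.ones(pred.shape, dtype=bool)
    else:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != pred.shape:
            raise InvalidInputError(
                f"fov shape {fov.shape} != mask shape {pred.shape}")

    p = pred[fov]
    t = truth[fov]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    acc_whole = _safe_ratio(int(np.sum(pred == truth)), pred.size)
    return SegmentationMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=_safe_ratio(tp, tp + fn),
        fpr=_safe_ratio(fp, fp + tn),
        accuracy=_safe_ratio(tp + tn, tp + fp + tn + fn),
        accuracy_whole_image=acc_whole,
    )


def fov_mask_from_rgb(image: np.ndarray,
                      thresholds: tuple = DEFAULT_FOV_THRESHOLDS) -> np.ndarray:
    """Field-of-view mask by per-channel thresholding of a colour image.

    A pixel belongs to the FOV when every channel strictly exceeds its
    threshold; afterwards only the largest 8-connected component is kept to
    drop speckle outside the aperture.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise InvalidInputError(
            "fov_mask_from_rgb needs a 3-channel image; "
            "pass an explicit mask for grayscale input")
    thresholds = np.asarray(thresholds, dtype=float)
    mask = np.all(image[:, :, :3].astype(float) > thresholds[None, None, :], axis=2)
    if not mask.any():
        return mask
    labels, n = _sk_label(mask, connectivity=2, return_num=True)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
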