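"""Segmentation evaluation metrics: accuracy, Dice, mIoU, HD95.

All metrics compare two integer class masks of equal shape.  Per-class
scores are macro-averaged over classes present in either mask; whether the
background class (0) participates is configurable (excluded by default, the
usual convention for foreground-structure reporting).

Empty-class conventions: Dice/IoU of a class absent from both masks is 1
(perfect vacuous agreement); HD95 of such a class is 0, and a class present
in exactly one mask receives the image diagonal as penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

__all__ = [
    "MetricsReport",
    "pixel_accuracy",
    "dice_score",
    "iou_score",
    "mean_iou",
    "hd95",
    "evaluate_masks",
]


@dataclass
class MetricsReport:
    """Per-class and mean segmentation scores on an evaluation set."""

    accuracy: float
    dice: float
    miou: float
    hd95: float
    per_class_dice: dict[int, float] = field(default_factory=dict)
    per_class_iou: dict[int, float] = field(default_factory=dict)
    per_class_hd95: dict[int, float] = field(default_factory=dict)
    n_images: int = 1
    classes_evaluated: tuple[int, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "dice": self.dice,
            "miou": self.miou,
            "hd95": self.hd95,
            "per_class_dice": {str(k): v for k, v in self.per_class_dice.items()},
            "per_class_iou": {str(k): v for k, v in self.per_class_iou.items()},
            "per_class_hd95": {str(k): v for k, v in self.per_class_hd95.items()},
            "n_images": self.n_images,
            "classes_evaluated": list(self.classes_evaluated),
        }


def _check_masks(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p, t


def pixel_accuracy(pred, truth) -> float:
    """Fraction of pixels whose predicted label matches the truth."""
    p, t = _check_masks(pred, truth)
    return float(np.mean(p == t))


def dice_score(pred, truth, c: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) for class ``c``; 1 if absent from both."""
    p, t = _check_masks(pred, truth)
    a = p == c
    b = t == c
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou_score(pred, truth, c: int) -> float:
    """Intersection over union for class ``c``; 1 if absent from both."""
    p, t = _check_masks(pred, truth)
    a = p == c
    b = t == c
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _present_classes(pred, truth, include_background: bool) -> list[int]:
    classes = sorted(set(np.unique(pred)) | set(np.unique(truth)))
    if not include_background:
        classes = [c for c in classes if c != 0]
    return [int(c) for c in classes]


def mean_iou(pred, truth, include_background: bool = False) -> float:
    """Mean IoU over classes present in either mask."""
    p, t = _check_masks(pred, truth)
    classes = _present_classes(p, t, include_background)
    if not classes:
        return 1.0
    return float(np.mean([iou_score(p, t, c) for c in classes]))


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    bnd = find_boundaries(mask.astype(bool), mode="inner")
    return np.argwhere(bnd)


def hd95(pred, truth, c: int) -> float:
    """95th-percentile symmetric boundary distance for class ``c``, in pixels.

    Pools nearest-neighbor distances from each mask's class boundary to the
    other's and takes the 95th percentile (linear interpolation between order
    statistics).  Class absent from both masks scores 0; absent from exactly
    one scores the image diagonal (maximal penalty).
    """
    p, t = _check_masks(pred, truth)
    a = p == c
    b = t == c
    if not a.any() and not b.any():
        return 0.0
    if a.any() != b.any():
        return float(np.hypot(*p.shape))
    pa = _boundary_points(a)
    pb = _boundary_points(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def evaluate_masks(preds, truths, include_background: bool = False) -> MetricsReport:
    """Aggregate metrics over a set of (pred, truth) mask pairs.

    Per-class scores are averaged over the images in which the class appears
    in either mask; the report's scalar fields are macro means over classes.
    """
    preds = [np.asarray(p) for p in preds]
    truths = [np.asarray(t) for t in truths]
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal, non-zero numbers of predictions and truths")

    all_classes: set[int] = set()
    for p, t in zip(preds, truths):
        all_classes.update(_present_classes(p, t, include_background))
    classes = sorted(all_classes)

    acc = float(np.mean([pixel_accuracy(p, t) for p, t in zip(preds, truths)]))
    per_dice: dict[int, float] = {}
    per_iou: dict[int, float] = {}
    per_hd: dict[int, float] = {}
    for c in classes:
        dices, ious, hds = [], [], []
        for p, t in zip(preds, truths):
            if (p == c).any() or (t == c).any():
                dices.append(dice_score(p, t, c))
                ious.append(iou_score(p, t, c))
                hds.append(hd95(p, t, c))
        per_dice[c] = float(np.mean(dices)) if dices else 1.0
        per_iou[c] = float(np.mean(ious)) if ious else 1.0
        per_hd[c] = float(np.mean(hds)) if hds else 0.0

    mean_dice = float(np.mean(list(per_dice.values()))) if classes else 1.0
    miou = float(np.mean(list(per_iou.values()))) if classes else 1.0
    mean_hd = float(np.mean(list(per_hd.values()))) if classes else 0.0
    return MetricsReport(
        accuracy=acc,
        dice=mean_dice,
        miou=miou,
        hd95=mean_hd,
        per_class_dice=per_dice,
        per_class_iou=per_iou,
        per_class_hd95=per_hd,
        n_images=len(preds),
        classes_evaluated=tuple(classes),
    )
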