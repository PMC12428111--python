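"""Per-pixel segmentation losses and statistical pixel filters.

Losses operate on a class-probability map ``pred`` of shape ``(C, P)`` (one
probability column per pixel, columns on the simplex) and a one-hot ground
truth ``truth`` of the same shape.  Two individual losses are provided:

- per-pixel cross-entropy, the natural rankable choice;
- a continuous Dice term: the hard Dice loss is computed on binarized maps
  and offers no per-pixel ranking, but its continuous counterpart decomposes
  into per-pixel contributions ``rho(yhat_cj, y_cj) = yhat_cj * y_cj /
  (sum_j yhat_cj^2 + sum_j y_cj^2)``, which are continuous and rankable.

The combined per-pixel loss is ``l_j = lambda_ce * CE_j + lambda_dc *
(1 - dice_factor * rho_j)`` with ``rho`` evaluated at the pixel's true class.
``dice_factor=1`` reproduces the continuous Dice loss exactly as defined
(perfect prediction scores 0.5 per class); ``dice_factor=2`` is the standard
soft-Dice convention whose minimum is 0 and is the training default.

Two image-level pixel filters support robust training:

- ``bottom_all_but_sigma``: keep pixels whose loss is at most the image mean
  plus one (population) standard deviation — discarding the extreme-loss
  pixels that most likely carry wrong annotations;
- ``top_k_pixels``: keep only the highest-loss fraction (hard-pixel mining).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LossWeights",
    "PixelLossMap",
    "as_probability_map",
    "as_one_hot",
    "one_hot_from_labels",
    "cross_entropy_per_pixel",
    "continuous_dice_rho",
    "continuous_dice_loss",
    "combined_pixel_loss",
    "bottom_all_but_sigma",
    "top_k_pixels",
]

#: probabilities are clipped to [CLIP_EPS, 1] before logarithms
CLIP_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Mixing weights of the combined per-pixel loss.

    ``lambda_ce`` and ``lambda_dc`` weight the cross-entropy and continuous
    Dice terms (defaults 0.3 / 0.7, the burn-segmentation setting).
    ``class_weights`` optionally re-weights classes in both terms.
    ``dice_factor`` scales the per-pixel Dice contribution: 2 is the standard
    soft-Dice convention (perfect prediction scores 0), 1 the verbatim
    continuous-Dice definition (perfect prediction scores 0.5 per class).
    """

    lambda_ce: float = 0.3
    lambda_dc: float = 0.7
    class_weights: Optional[tuple[float, ...]] = None
    dice_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda_ce < 0 or self.lambda_dc < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.lambda_ce + self.lambda_dc <= 0:
            raise ValueError("lambda_ce + lambda_dc must be positive")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


@dataclass
class PixelLossMap:
    """Per-pixel losses of one image plus the boolean retention mask."""

    losses: np.ndarray
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.losses = np.asarray(self.losses, dtype=float).ravel()
        if self.losses.size == 0:
            raise ValueError("pixel loss map must contain at least one pixel")
        if not np.all(np.isfinite(self.losses)) or np.any(self.losses < 0):
            raise ValueError("pixel losses must be finite and non-negative")
        if self.retained is None:
            self.retained = np.ones(self.losses.shape, dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool).ravel()
            if self.retained.shape != self.losses.shape:
                raise ValueError("retention mask must match losses in length")
            if not self.retained.any():
                raise ValueError("at least one pixel must be retained")

    @property
    def n_pixels(self) -> int:
        return int(self.losses.size)

    def retained_mean(self) -> float:
        return float(np.mean(self.losses[self.retained]))


def as_probability_map(pred) -> np.ndarray:
    """Validate a (C, P) class-probability map (columns on the simplex)."""
    arr = np.asarray(pred, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 1:
        raise ValueError(f"probability map must be (C>=2, P>=1), got {arr.shape}")
    if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    col = arr.sum(axis=0)
    if np.any(np.abs(col - 1.0) > 1e-6):
        raise ValueError("probability columns must sum to 1 (within 1e-6)")
    return arr


def as_one_hot(truth) -> np.ndarray:
    """Validate a (C, P) one-hot mask (exactly one 1 per pixel column)."""
    arr = np.asarray(truth, dtype=float)
    if arr.ndim != 2:
        raise ValueError("one-hot mask must be 2-D (C, P)")
    if not np.all((arr == 0) | (arr == 1)) or np.any(arr.sum(axis=0) != 1):
        raise ValueError("mask must be one-hot: exactly one 1 per pixel")
    return arr


def one_hot_from_labels(labels, n_classes: int) -> np.ndarray:
    """Encode an integer class mask (any shape) as a (C, P) one-hot array."""
    lab = np.asarray(labels).ravel()
    if lab.min() < 0 or lab.max() >= n_classes:
        raise ValueError("class ids out of range")
    out = np.zeros((n_classes, lab.size), dtype=float)
    out[lab, np.arange(lab.size)] = 1.0
    return out


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")


def _class_weight_vector(class_weights, n_classes: int) -> np.ndarray:
    if class_weights is None:
        return np.ones(n_classes)
    w = np.asarray(class_weights, dtype=float)
    if w.shape != (n_classes,):
        raise ValueError(f"expected {n_classes} class weights, got {w.shape}")
    return w


def cross_entropy_per_pixel(pred, truth, class_weights=None) -> PixelLossMap:
    """Per-pixel cross-entropy ``l_j = -w_c(j) log yhat_c(j),j``.

    ``c(j)`` is the true class of pixel ``j``; probabilities are clipped to
    ``[1e-12, 1]`` before the logarithm so all losses stay finite.
    """
    pred = as_probability_map(pred)
    truth = as_one_hot(truth)
    _check_shapes(pred, truth)
    w = _class_weight_vector(class_weights, pred.shape[0])
    true_class = np.argmax(truth, axis=0)
    p_true = np.clip(pred[true_class, np.arange(pred.shape[1])], CLIP_EPS, 1.0)
    losses = -w[true_class] * np.log(p_true)
    return PixelLossMap(losses)


def continuous_dice_rho(pred, truth, c: int) -> np.ndarray:
    """Per-pixel continuous-Dice contributions for class ``c``.

    ``rho_cj = yhat_cj * y_cj / (sum_j yhat_cj^2 + sum_j y_cj^2)``.  The
    per-class sum of ``rho`` lies in [0, 0.5]; it equals 0.5 exactly for a
    perfect one-hot prediction.  A class absent from both maps (zero
    denominator) yields all-zero contributions.
    """
    pred = as_probability_map(pred)
    truth = as_one_hot(truth)
    _check_shapes(pred, truth)
    if not 0 <= c < pred.shape[0]:
        raise ValueError(f"class {c} out of range for C={pred.shape[0]}")
    denom = float(np.sum(pred[c] ** 2) + np.sum(truth[c] ** 2))
    if denom == 0.0:
        return np.zeros(pred.shape[1])
    return pred[c] * truth[c] / denom


def continuous_dice_loss(
    pred, truth, dice_factor: float = 2.0, class_weights=None
) -> tuple[float, np.ndarray]:
    """Continuous Dice loss and its per-pixel contributions.

    Returns ``(loss, per_pixel)`` where ``loss = mean_c w_c (1 - dice_factor *
    sum_j rho_cj)`` over classes present in truth or prediction, and
    ``per_pixel[j] = 1 - dice_factor * rho_j`` at each pixel's true class —
    the rankable form used by the combined loss.
    """
    pred = as_probability_map(pred)
    truth = as_one_hot(truth)
    _check_shapes(pred, truth)
    C, P = pred.shape
    w = _class_weight_vector(class_weights, C)
    true_class = np.argmax(truth, axis=0)
    per_class = []
    rho_true = np.zeros(P)
    for c in range(C):
        denom = float(np.sum(pred[c] ** 2) + np.sum(truth[c] ** 2))
        if denom == 0.0:
            continue  # class absent everywhere: excluded from the average
        rho_c = pred[c] * truth[c] / denom
        per_class.append(w[c] * (1.0 - dice_factor * float(np.sum(rho_c))))
        sel = true_class == c
        rho_true[sel] = rho_c[sel]
    loss = float(np.mean(per_class)) if per_class else 0.0
    per_pixel = 1.0 - dice_factor * rho_true
    return loss, per_pixel


def combined_pixel_loss(pred, truth, w: LossWeights | None = None,
                        dice_factor: float | None = None) -> PixelLossMap:
    """Combined per-pixel loss ``lambda_ce * CE_j + lambda_dc * (1 - f * rho_j)``.

    ``rho_j`` is the continuous-Dice contribution at the pixel's true class;
    ``f`` is ``dice_factor`` (argument overrides ``w.dice_factor``).
    """
    if w is None:
        w = LossWeights()
    f = w.dice_factor if dice_factor is None else dice_factor
    ce = cross_entropy_per_pixel(pred, truth, w.class_weights).losses
    _, dc_pixel = continuous_dice_loss(pred, truth, f, w.class_weights)
    losses = w.lambda_ce * ce + w.lambda_dc * dc_pixel
    # dice_factor * rho <= 1 holds since sum_c rho <= 1/2 <= 1/f for f <= 2,
    # so the Dice contribution is non-negative; assert against regressions
    if np.any(losses < -1e-9):
        raise FloatingPointError("combined pixel loss went negative")
    return PixelLossMap(np.maximum(losses, 0.0))


def bottom_all_but_sigma(pl: PixelLossMap) -> PixelLossMap:
    """Retain pixels whose loss is at most mean + one standard deviation.

    The threshold uses the population standard deviation of the image's own
    pixel losses and a non-strict comparison, so a constant loss map retains
    every pixel.  The retained-set mean never exceeds the full mean.
    """
    losses = pl.losses
    thr = float(np.mean(losses) + np.std(losses))
    retained = losses <= thr
    if not retained.any():  # unreachable with a non-strict threshold; guard anyway
        retained = losses == losses.min()
    return PixelLossMap(losses, retained)


def top_k_pixels(pl: PixelLossMap, fraction: float) -> PixelLossMap:
    """Retain only the highest-loss fraction of pixels (hard-pixel mining).

    The count is ``max(1, ceil(fraction * P))``; ties keep the earliest pixel
    indices (stable order).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    losses = pl.losses
    count = max(1, int(np.ceil(fraction * losses.size)))
    # stable sort descending: sort ascending on (-loss) with stable kind
    order = np.argsort(-losses, kind="stable")
    retained = np.zeros(losses.shape, dtype=bool)
    retained[order[:count]] = True
    return PixelLossMap(losses, retained)
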