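"""Nested image/pixel loss envelope with rank-selection training schedules.

For segmentation, the N individual losses decompose as N = I x P (I images of
P pixels each) and the plain mean objective becomes a pair of nested sums.
The envelope generalizes both levels:

- image level: each image's scalar loss receives a rank-dependent weight —
  all images (``erm``), the top-k fraction (``atk``, active from the second
  epoch), or a window that shrinks from all images toward the top 5 percent
  over training (``atk_dec``).  The hard window indicator can be replaced by
  a sigmoid boxcar of sharpness alpha (``sm`` fixed at 20, ``sm_inc``
  decaying linearly from 20 to 1), which smooths the selection and prevents
  the oscillation that abrupt re-selection causes;
- pixel level: within each image, keep all pixels (``all``), only the top
  10 percent hardest (``tk``), or the "bottom all but sigma" set — pixels
  whose loss is at most the image mean plus one standard deviation
  (``bsigma``), discarding the likely-mislabeled extremes.

Image ranks are maintained across an epoch by incremental insertion of each
batch's losses into a pre-sorted structure (no full re-sort); when the
structure holds only part of the epoch, ranks are extrapolated to the full
image count.  Selection weights and retention masks are computed from loss
values and treated as constants during the gradient step (stop-gradient
semantics): the sort is never differentiated through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from segrank.pixel_losses import (
    LossWeights,
    PixelLossMap,
    bottom_all_but_sigma,
    top_k_pixels,
)
from segrank.rank_aggregation import boxcar_selector, incremental_sorted_insert

__all__ = [
    "IMAGE_STRATEGIES",
    "SMOOTHING_MODES",
    "PIXEL_STRATEGIES",
    "StrategyConfig",
    "EpochRankState",
    "schedule_k",
    "schedule_alpha",
    "image_loss",
    "nested_loss",
    "epoch_reset",
]

IMAGE_STRATEGIES = ("erm", "atk", "atk_dec")
SMOOTHING_MODES = ("none", "sm", "sm_inc")
PIXEL_STRATEGIES = ("all", "tk", "bsigma")


@dataclass(frozen=True)
class StrategyConfig:
    """Full training recipe: image-level strategy, smoothing schedule,
    pixel-level strategy, loss weights and schedule endpoints.

    Defaults follow the reference recipe: top-k window of 10 percent
    (``atk``), decreasing to 5 percent (``atk_dec``), alpha from 20 down
    to 1, pixel top-k fraction 10 percent.
    """

    image_strategy: str = "erm"
    smoothing: str = "none"
    pixel_strategy: str = "all"
    atk_fraction: float = 0.10
    final_k_fraction: float = 0.05
    alpha_start: float = 20.0
    alpha_end: float = 1.0
    total_epochs: int = 30
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    pixel_topk_fraction: float = 0.10
    pixel_start_epoch: int = 3
    normalization: str = "effective_weight"

    def __post_init__(self) -> None:
        if self.image_strategy not in IMAGE_STRATEGIES:
            raise ValueError(f"image_strategy must be one of {IMAGE_STRATEGIES}")
        if self.smoothing not in SMOOTHING_MODES:
            raise ValueError(f"smoothing must be one of {SMOOTHING_MODES}")
        if self.pixel_strategy not in PIXEL_STRATEGIES:
            raise ValueError(f"pixel_strategy must be one of {PIXEL_STRATEGIES}")
        for name in ("atk_fraction", "final_k_fraction", "pixel_topk_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not self.alpha_start >= self.alpha_end > 0:
            raise ValueError("require alpha_start >= alpha_end > 0")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if self.pixel_start_epoch < 0:
            raise ValueError("pixel_start_epoch must be >= 0")

    @property
    def token(self) -> str:
        """Compact strategy token, e.g. ``atk_dec+sm_inc+bsigma``."""
        return f"{self.image_strategy}+{self.smoothing}+{self.pixel_strategy}"


@dataclass
class EpochRankState:
    """Ascending per-image scalar losses accumulated during the current epoch."""

    sorted_image_losses: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sorted_image_losses)


def epoch_reset(state: EpochRankState | None = None) -> EpochRankState:
    """Clear (or create) the epoch rank state.

    A fresh state carries no ranking information, so the first batch after a
    reset is weighted uniformly.
    """
    if state is None:
        return EpochRankState()
    state.sorted_image_losses.clear()
    return state


def schedule_k(epoch: int, cfg: StrategyConfig, n_images: int) -> tuple[int, int]:
    """Image-selection window ``(k, i0)`` for the given epoch (0-based).

    ``erm``: all images, always.  ``atk``: all images in the first epoch (all
    losses must be seen before ranking means anything), then a fixed top
    window of ``atk_fraction`` of the images.  ``atk_dec``: the window width
    shrinks linearly from all images to ``final_k_fraction`` at the final
    epoch.  The window is always the top one: ``i0 = I - k + 1``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside schedule of {cfg.total_epochs}")
    if cfg.image_strategy == "erm":
        return n_images, 1
    if cfg.image_strategy == "atk":
        if epoch == 0:
            return n_images, 1
        k = max(1, math.ceil(cfg.atk_fraction * n_images))
        return k, n_images - k + 1
    # atk_dec: linear interpolation from k=I (epoch 0) to the final fraction
    k_final = max(1, math.ceil(cfg.final_k_fraction * n_images))
    if cfg.total_epochs == 1:
        k = n_images
    else:
        t = epoch / (cfg.total_epochs - 1)
        k = int(round(n_images + (k_final - n_images) * t))
    k = min(max(k, 1), n_images)
    return k, n_images - k + 1


def schedule_alpha(epoch: int, cfg: StrategyConfig) -> float:
    """Selector sharpness for the given epoch.

    ``none`` returns ``inf`` (exact indicator); ``sm`` holds ``alpha_start``;
    ``sm_inc`` decays linearly from ``alpha_start`` to ``alpha_end`` across
    the schedule (smoothing increases as alpha decreases).
    """
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside schedule of {cfg.total_epochs}")
    if cfg.smoothing == "none":
        return math.inf
    if cfg.smoothing == "sm" or cfg.total_epochs == 1:
        return cfg.alpha_start
    t = epoch / (cfg.total_epochs - 1)
    return cfg.alpha_start + (cfg.alpha_end - cfg.alpha_start) * t


def image_loss(pl: PixelLossMap, cfg: StrategyConfig) -> tuple[float, np.ndarray]:
    """Scalar per-image loss: mean of the retained pixel losses.

    Applies the configured pixel filter first; returns ``(loss, retained)``.
    """
    if cfg.pixel_strategy == "tk":
        filtered = top_k_pixels(pl, cfg.pixel_topk_fraction)
    elif cfg.pixel_strategy == "bsigma":
        filtered = bottom_all_but_sigma(pl)
    else:
        filtered = PixelLossMap(pl.losses)
    return filtered.retained_mean(), filtered.retained


def _rank_weights(
    ranks: Sequence[float], k: int, i0: int, alpha: float
) -> np.ndarray:
    r = np.asarray(ranks, dtype=float)
    if math.isinf(alpha):
        return ((r >= i0) & (r <= i0 + k - 1)).astype(float)
    # half-rank offset so integer ranks sit symmetrically inside the window
    return np.asarray(boxcar_selector(r, i0 - 0.5, float(k), alpha), dtype=float)


def nested_loss(
    state: EpochRankState,
    batch_image_losses: Sequence[float],
    epoch: int,
    cfg: StrategyConfig,
    n_images: int,
) -> tuple[float, np.ndarray]:
    """Aggregate a batch of per-image losses under the image-level strategy.

    The batch losses are inserted into the epoch's pre-sorted structure and
    each image's rank is read off the merged sequence; while the structure
    holds only part of the epoch, ranks are rescaled by ``I / len(state)`` so
    the selection window (defined on full-epoch ranks) applies.  Image
    weights come from the hard indicator (``smoothing='none'``) or the
    sigmoid boxcar; the batch loss is the weighted sum divided by the
    normalizer (default: total weight, a weighted mean).  Under ``erm`` all
    weights are 1 and the result is the plain batch mean.  A batch whose
    total weight is numerically zero falls back to uniform weights, so no
    batch can lose its learning signal entirely.

    Returns ``(loss, weights)``; ``state`` is updated in place.
    """
    losses = np.asarray(batch_image_losses, dtype=float).ravel()
    if losses.size == 0:
        raise ValueError("batch must contain at least one image loss")
    b = losses.size

    state_was_empty = len(state) == 0
    merged, ranks = incremental_sorted_insert(state.sorted_image_losses, losses)
    state.sorted_image_losses = merged

    if cfg.image_strategy == "erm":
        weights = np.ones(b)
        return float(np.mean(losses)), weights

    if state_was_empty:
        # no ranking information yet this epoch: uniform weights
        weights = np.ones(b)
        return float(np.mean(losses)), weights

    k, i0 = schedule_k(epoch, cfg, n_images)
    alpha = schedule_alpha(epoch, cfg)
    scale = n_images / len(merged)
    scaled_ranks = np.asarray(ranks, dtype=float) * scale
    weights = _rank_weights(scaled_ranks, k, i0, alpha)

    wsum = float(np.sum(weights))
    if wsum <= 1e-12:
        weights = np.ones(b)
        wsum = float(b)

    if cfg.normalization == "paper_N":
        norm = float(b)
    elif cfg.normalization == "paper_k":
        norm = max(1.0, k * b / n_images)
    else:
        norm = wsum
    return float(np.sum(weights * losses) / norm), weights
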