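"""Desk-scale training harness binding the loss envelope to tiny predictors.

The envelope is predictor-agnostic: anything that maps an image to a class
probability map can be trained with it.  The bundled predictors are
deliberately small multinomial-logistic ("softmax") pixel classifiers so that
full ablation grids run in seconds on one CPU:

- ``linear_per_pixel``: a trainable softmax head over fixed multiscale
  intensity features (raw value, Gaussian-smoothed copies, local contrast);
- ``shallow_conv``: the same head over a fixed random 3x3 convolutional
  feature bank (random-feature convolution: filters are drawn once from the
  predictor seed and never trained).

Gradients are computed analytically.  Selection weights and pixel-retention
masks are treated as constants within a step (stop-gradient): the gradient
of the combined cross-entropy + continuous-Dice loss flows through the
retained pixels' cross-entropy terms and through the continuous-Dice
contributions, including the coupling introduced by the per-class Dice
denominator, and each image's gradient is scaled by its (normalized)
rank-selection weight.  Training is plain gradient descent with a fixed
learning rate, sequential batches re-shuffled every epoch under the
strategy seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from segrank.envelope import (
    EpochRankState,
    StrategyConfig,
    epoch_reset,
    image_loss,
    nested_loss,
    schedule_alpha,
    schedule_k,
)
from segrank.metrics import MetricsReport, evaluate_masks
from segrank.pixel_losses import (
    CLIP_EPS,
    LossWeights,
    combined_pixel_loss,
    one_hot_from_labels,
)
from segrank.synthetic_data import SegmentationSample, SyntheticConfig, generate_dataset

__all__ = [
    "PredictorSpec",
    "SoftmaxPixelPredictor",
    "RunRecord",
    "ConvergenceError",
    "train",
    "ablate",
    "evaluate_predictor",
    "noise_robustness_experiment",
]


class ConvergenceError(RuntimeError):
    """Raised when training produces a non-finite or runaway loss."""


@dataclass(frozen=True)
class PredictorSpec:
    """Trainable per-pixel classifier settings.

    ``kind`` selects the feature map; the trainable part is always a softmax
    head, so parameter counts stay tiny and acceptance runs finish on one
    CPU.  ``n_filters`` only applies to ``shallow_conv``.
    """

    kind: str = "linear_per_pixel"
    n_classes: int = 3
    n_filters: int = 8
    optimizer: str = "adam"
    learning_rate: float = 0.0
    batch_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_per_pixel", "shallow_conv"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.optimizer not in ("adam", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be >= 0 and batch_size >= 1")

    @property
    def step_size(self) -> float:
        """Learning rate, defaulting per optimizer: adaptive-moment steps
        need a small value (0.5) while plain gradient descent on these
        well-conditioned O(1) features needs a large one (30)."""
        if self.learning_rate > 0:
            return self.learning_rate
        return 0.5 if self.optimizer == "adam" else 30.0


class SoftmaxPixelPredictor:
    """Softmax head over a fixed per-pixel feature map.

    Weights ``W`` have shape (C, F); logits for an image are ``W @ phi`` with
    ``phi`` of shape (F, P), giving a class probability column per pixel.
    """

    def __init__(self, spec: PredictorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        if spec.kind == "shallow_conv":
            self.filters = rng.normal(size=(spec.n_filters, 3, 3))
            self.filters /= np.sqrt((self.filters ** 2).sum((1, 2), keepdims=True))
            n_features = 2 + spec.n_filters  # bias + intensity + filter responses
        else:
            self.filters = None
            n_features = 6  # bias, intensity, 3 Gaussian scales, local contrast
        self.W = rng.normal(scale=0.01, size=(spec.n_classes, n_features))

    # -- feature map ------------------------------------------------------
    def features(self, image: np.ndarray) -> np.ndarray:
        """Fixed per-pixel features, shape (F, P)."""
        img = np.asarray(image, dtype=float)
        p = img.size
        if self.spec.kind == "shallow_conv":
            chans = [np.ones(p), img.ravel()]
            for f in self.filters:
                resp = ndimage.convolve(img, f, mode="nearest")
                chans.append(np.tanh(resp).ravel())
        else:
            # centered + band-pass channels: same linear span as raw
            # multiscale Gaussians but far better conditioned for plain GD
            g1 = ndimage.gaussian_filter(img, 1.0)
            g2 = ndimage.gaussian_filter(img, 2.0)
            g4 = ndimage.gaussian_filter(img, 4.0)
            chans = [np.ones(p), (2 * (img - 0.5)).ravel(),
                     (2 * (g2 - 0.5)).ravel(), (8 * (img - g1)).ravel(),
                     (8 * (g1 - g2)).ravel(), (8 * (g2 - g4)).ravel()]
        return np.stack(chans)

    def forward(self, feats: np.ndarray) -> np.ndarray:
        """Class probabilities (C, P) for precomputed features."""
        z = self.W @ feats
        z -= z.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        probs = self.forward(self.features(image))
        return np.argmax(probs, axis=0).reshape(image.shape)


@dataclass
class RunRecord:
    """Per-epoch training trace plus the final evaluation report."""

    epoch_losses: list[float] = field(default_factory=list)
    selected_images: list[int] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    # pixel-retention statistics (filled when pixel filtering is active and
    # the samples expose their corrupted-pixel maps)
    discarded_pixels: list[int] = field(default_factory=list)
    discarded_corrupted: list[int] = field(default_factory=list)
    total_pixels: int = 0
    total_corrupted: int = 0
    metrics: Optional[MetricsReport] = None
    strategy_token: str = ""
    seed: int = 0
    converged: bool = True

    def discard_enrichment(self, epoch: int = -1) -> Optional[float]:
        """Corrupted fraction among discarded pixels over the corruption base
        rate; > 1 means the filter preferentially removes mislabeled pixels."""
        if not self.discarded_pixels or self.total_corrupted == 0:
            return None
        n_disc = self.discarded_pixels[epoch]
        if n_disc == 0:
            return None
        frac = self.discarded_corrupted[epoch] / n_disc
        base = self.total_corrupted / self.total_pixels
        return frac / base


def pixel_loss_gradient(
    probs: np.ndarray,
    onehot: np.ndarray,
    retained: np.ndarray,
    w: LossWeights,
) -> np.ndarray:
    """Analytic gradient of the retained-pixel mean combined loss w.r.t. logits.

    The per-image loss is the mean over retained pixels of
    ``lambda_ce * CE_j + lambda_dc * (1 - f * rho_j)`` with ``rho`` at the
    pixel's true class.  The continuous-Dice denominator couples all pixels
    of a class, so its gradient reaches every pixel, retained or not.
    Returns (C, P), the gradient w.r.t. the softmax logits.
    """
    C, P = probs.shape
    true_class = np.argmax(onehot, axis=0)
    cw = (np.ones(C) if w.class_weights is None
          else np.asarray(w.class_weights, dtype=float))
    n_ret = int(retained.sum())
    cols = np.arange(P)

    g = np.zeros((C, P))
    # cross-entropy: -w_c log p at the true class, retained pixels only
    p_true = np.maximum(probs[true_class, cols], CLIP_EPS)
    ce_coef = np.where(retained, -w.lambda_ce * cw[true_class] / (n_ret * p_true), 0.0)
    g[true_class, cols] += ce_coef

    # continuous Dice: d/dp of -(lambda_dc * f / n_ret) * sum_{j in R} rho_j
    f = w.dice_factor
    denom = (probs ** 2).sum(axis=1) + (onehot ** 2).sum(axis=1)  # (C,)
    coef = -w.lambda_dc * f / n_ret
    for c in range(C):
        if denom[c] == 0.0:
            continue
        in_class = (true_class == c) & retained
        s_c = float(probs[c, in_class].sum())
        grad_rho = -2.0 * probs[c] * s_c / denom[c] ** 2
        grad_rho[in_class] += 1.0 / denom[c]
        g[c] += coef * grad_rho

    # softmax backprop: dL/dz = p * (g - sum_c g_c p_c)
    inner = (g * probs).sum(axis=0, keepdims=True)
    return probs * (g - inner)


def _batch_indices(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def train(
    data: Sequence[SegmentationSample],
    predictor: PredictorSpec,
    strategy: StrategyConfig,
    eval_data: Optional[Sequence[SegmentationSample]] = None,
) -> tuple[SoftmaxPixelPredictor, RunRecord]:
    """Gradient-descent training of a pixel predictor under the loss envelope.

    Trains on the noisy masks; the optional ``eval_data`` is scored against
    its clean masks at the end.  Deterministic given the data, predictor seed
    and strategy seed.  Raises :class:`ConvergenceError` on a non-finite or
    runaway (> 1e6) loss.
    """
    if not data:
        raise ValueError("training data must be non-empty")
    model = SoftmaxPixelPredictor(predictor)
    n_images = len(data)
    feats = [model.features(s.image) for s in data]
    onehots = [one_hot_from_labels(s.noisy_mask, predictor.n_classes) for s in data]
    corrupted = [s.corrupted.ravel() for s in data]

    record = RunRecord(strategy_token=strategy.token, seed=strategy.seed)
    record.total_pixels = sum(c.size for c in corrupted)
    record.total_corrupted = int(sum(c.sum() for c in corrupted))

    rng = np.random.default_rng(strategy.seed)
    lr = predictor.step_size
    # adaptive-moment (Adam) optimizer state; plain GD when disabled
    adam_m = np.zeros_like(model.W)
    adam_v = np.zeros_like(model.W)
    adam_t = 0
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8

    for epoch in range(strategy.total_epochs):
        state = epoch_reset()
        k, i0 = schedule_k(epoch, strategy, n_images)
        alpha = schedule_alpha(epoch, strategy)
        # pixel filtering activates once every loss has been seen under a
        # settled model (same rule as the image-level top-k window)
        if epoch < strategy.pixel_start_epoch:
            epoch_strategy = replace(strategy, pixel_strategy="all")
        else:
            epoch_strategy = strategy
        batch_losses_sum = 0.0
        n_batches = 0
        n_selected = 0
        disc = disc_corr = 0

        for batch in _batch_indices(n_images, predictor.batch_size, rng):
            img_losses = []
            grads = []
            for idx in batch:
                probs = model.forward(feats[idx])
                pl = combined_pixel_loss(probs, onehots[idx], strategy.weights)
                loss_i, retained = image_loss(pl, epoch_strategy)
                img_losses.append(loss_i)
                grads.append(pixel_loss_gradient(probs, onehots[idx],
                                                 retained, strategy.weights))
                if epoch_strategy.pixel_strategy != "all":
                    dropped = ~retained
                    disc += int(dropped.sum())
                    disc_corr += int((dropped & corrupted[idx]).sum())

            batch_loss, weights = nested_loss(state, img_losses, epoch,
                                              strategy, n_images)
            if not math.isfinite(batch_loss) or batch_loss > 1e6:
                raise ConvergenceError(
                    f"training diverged at epoch {epoch}, batch {n_batches} "
                    f"(loss={batch_loss})"
                )
            # gradient normalizer mirrors the loss normalizer in nested_loss
            if strategy.normalization == "paper_N":
                norm = float(len(batch))
            elif strategy.normalization == "paper_k":
                norm = max(1.0, k * len(batch) / n_images)
            else:
                wsum = float(weights.sum())
                norm = wsum if wsum > 1e-12 else float(len(batch))
            grad_W = np.zeros_like(model.W)
            for wgt, idx, gz in zip(weights, batch, grads):
                if wgt == 0.0:
                    continue
                grad_W += (wgt / norm) * (gz @ feats[idx].T)
            if predictor.optimizer == "adam":
                adam_t += 1
                adam_m = beta1 * adam_m + (1 - beta1) * grad_W
                adam_v = beta2 * adam_v + (1 - beta2) * grad_W ** 2
                m_hat = adam_m / (1 - beta1 ** adam_t)
                v_hat = adam_v / (1 - beta2 ** adam_t)
                model.W -= lr * m_hat / (np.sqrt(v_hat) + adam_eps)
            else:
                model.W -= lr * grad_W

            batch_losses_sum += batch_loss
            n_batches += 1
            n_selected += int(np.sum(weights > 0.5))

        record.epoch_losses.append(batch_losses_sum / n_batches)
        record.selected_images.append(n_selected)
        record.alphas.append(alpha if math.isfinite(alpha) else float("inf"))
        record.discarded_pixels.append(disc)
        record.discarded_corrupted.append(disc_corr)

    if eval_data is not None:
        record.metrics = evaluate_predictor(model, eval_data)
    return model, record


def evaluate_predictor(
    model: SoftmaxPixelPredictor,
    samples: Sequence[SegmentationSample],
    include_background: bool = False,
) -> MetricsReport:
    """Score predicted masks against the clean ground-truth masks."""
    preds = [model.predict_mask(s.image) for s in samples]
    truths = [s.clean_mask for s in samples]
    return evaluate_masks(preds, truths, include_background=include_background)


# the strategy-grid tokens: (image_strategy, smoothing, pixel_strategy)
DEFAULT_GRID: tuple[tuple[str, str, str], ...] = (
    ("erm", "none", "all"),
    ("atk", "none", "all"),
    ("atk_dec", "none", "all"),
    ("atk_dec", "sm", "all"),
    ("atk_dec", "sm_inc", "all"),
    ("atk_dec", "sm_inc", "tk"),
    ("atk_dec", "sm_inc", "bsigma"),
)


def ablate(
    data: Sequence[SegmentationSample],
    eval_data: Sequence[SegmentationSample],
    predictor: PredictorSpec,
    grid: Sequence[tuple[str, str, str]] = DEFAULT_GRID,
    base_strategy: Optional[StrategyConfig] = None,
    seeds: Sequence[int] = (0,),
):
    """Run the strategy grid and tabulate Accuracy/Dice/mIoU/HD95 per cell.

    Every cell shares the data and the predictor seed; cells that diverge are
    reported as ``"nc"`` (not converged) without aborting the sweep.  With
    several seeds, mean and standard deviation columns are reported.
    Returns a pandas DataFrame indexed by strategy token.
    """
    import pandas as pd

    base = base_strategy or StrategyConfig()
    rows = []
    for img_s, smooth, pix_s in grid:
        token = f"{img_s}+{smooth}+{pix_s}"
        scores: dict[str, list[float]] = {m: [] for m in
                                          ("accuracy", "dice", "miou", "hd95")}
        failed = False
        for seed in seeds:
            cfg = replace(base, image_strategy=img_s, smoothing=smooth,
                          pixel_strategy=pix_s, seed=seed)
            try:
                _, rec = train(data, predictor, cfg, eval_data=eval_data)
            except ConvergenceError:
                failed = True
                break
            rep = rec.metrics
            scores["accuracy"].append(rep.accuracy)
            scores["dice"].append(rep.dice)
            scores["miou"].append(rep.miou)
            scores["hd95"].append(rep.hd95)
        row: dict[str, object] = {"strategy": token}
        for m, vals in scores.items():
            if failed or not vals:
                row[m] = "nc"
                if len(seeds) > 1:
                    row[f"{m}_sd"] = "nc"
            else:
                row[m] = float(np.mean(vals))
                if len(seeds) > 1:
                    row[f"{m}_sd"] = float(np.std(vals, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("strategy")


def noise_robustness_experiment(
    seed: int,
    n_train: int = 60,
    n_test: int = 24,
    size: int = 64,
    n_classes: int = 3,
    boundary_noise_px: int = 3,
    noise_fraction: float = 0.3,
    epochs: int = 30,
    control: bool = False,
    predictor: Optional[PredictorSpec] = None,
) -> dict:
    """One seed of the mechanism-replication experiment.

    Trains the plain-mean baseline (``erm+none+all``) and the full robust
    recipe (``atk_dec+sm_inc+bsigma``) on the same synthetic noisy-boundary
    dataset and scores both on a clean-labeled test set.  With
    ``control=True`` the data is the homogenized zero-noise control, where
    pixel labels are effectively correct and the filtering advantage is
    expected to vanish.

    Returns a dict with test Dice for both strategies, the Dice gap, and the
    corrupted-pixel enrichment among filter-discarded pixels (last epoch).
    """
    noise_px = 0 if control else boundary_noise_px
    common = dict(height=size, width=size, n_classes=n_classes,
                  boundary_noise_px=noise_px, noise_fraction=noise_fraction,
                  homogenize=control)
    train_cfg = SyntheticConfig(n_images=n_train, seed=seed, **common)
    test_cfg = SyntheticConfig(n_images=n_test, seed=seed + 100_003, **common)
    train_set, _ = generate_dataset(train_cfg)
    test_set, _ = generate_dataset(test_cfg)

    spec = predictor or PredictorSpec(n_classes=n_classes, seed=seed)
    erm_cfg = StrategyConfig(image_strategy="erm", smoothing="none",
                             pixel_strategy="all", total_epochs=epochs,
                             seed=seed)
    full_cfg = StrategyConfig(image_strategy="atk_dec", smoothing="sm_inc",
                              pixel_strategy="bsigma", total_epochs=epochs,
                              seed=seed)
    _, rec_erm = train(train_set, spec, erm_cfg, eval_data=test_set)
    _, rec_full = train(train_set, spec, full_cfg, eval_data=test_set)

    return {
        "seed": seed,
        "control": control,
        "dice_erm": rec_erm.metrics.dice,
        "dice_full": rec_full.metrics.dice,
        "dice_gap": rec_full.metrics.dice - rec_erm.metrics.dice,
        "corruption_rate": rec_full.total_corrupted / rec_full.total_pixels,
        "discard_enrichment": rec_full.discard_enrichment(),
        "record_erm": rec_erm,
        "record_full": rec_full,
    }
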