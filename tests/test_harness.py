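"""Tests for the training harness: gradients, training loop, ablation."""

import numpy as np
import pytest

from segrank.envelope import StrategyConfig
from segrank.harness import (
    DEFAULT_GRID,
    PredictorSpec,
    SoftmaxPixelPredictor,
    ablate,
    evaluate_predictor,
    noise_robustness_experiment,
    pixel_loss_gradient,
    train,
)
from segrank.pixel_losses import LossWeights, combined_pixel_loss, one_hot_from_labels
from segrank.synthetic_data import SyntheticConfig, generate_dataset

TINY = dict(n_images=6, height=32, width=32, n_classes=3, seed=3)


def _softmax(z):
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def _retained_mean_loss(z, onehot, retained, w):
    pl = combined_pixel_loss(_softmax(z), onehot, w)
    return float(np.mean(pl.losses[retained]))


# -- analytic gradient ---------------------------------------------------------

@pytest.mark.parametrize("with_filter", [False, True])
@pytest.mark.parametrize("class_weights", [None, (1.0, 2.0, 0.5)])
def test_pixel_loss_gradient_matches_finite_differences(with_filter, class_weights):
    rng = np.random.default_rng(42)
    C, P = 3, 12
    z = rng.normal(size=(C, P))
    onehot = one_hot_from_labels(rng.integers(0, C, size=P), C)
    retained = np.ones(P, dtype=bool)
    if with_filter:
        retained[rng.permutation(P)[: P // 3]] = False
    w = LossWeights(class_weights=class_weights)

    grad = pixel_loss_gradient(_softmax(z), onehot, retained, w)
    eps = 1e-6
    for _ in range(20):
        c, p = rng.integers(0, C), rng.integers(0, P)
        zp, zm = z.copy(), z.copy()
        zp[c, p] += eps
        zm[c, p] -= eps
        fd = (_retained_mean_loss(zp, onehot, retained, w)
              - _retained_mean_loss(zm, onehot, retained, w)) / (2 * eps)
        assert grad[c, p] == pytest.approx(fd, abs=1e-6)


# -- predictor -----------------------------------------------------------------

def test_predictor_spec_validation_and_step_size():
    with pytest.raises(ValueError):
        PredictorSpec(kind="mlp")
    with pytest.raises(ValueError):
        PredictorSpec(optimizer="sgd")
    with pytest.raises(ValueError):
        PredictorSpec(n_classes=1)
    with pytest.raises(ValueError):
        PredictorSpec(learning_rate=-1.0)
    assert PredictorSpec(optimizer="adam").step_size == 0.5
    assert PredictorSpec(optimizer="gd").step_size == 30.0
    assert PredictorSpec(learning_rate=0.01).step_size == 0.01


def test_predictor_shapes_and_determinism():
    img = np.random.default_rng(0).uniform(size=(24, 24))
    for kind in ("linear_per_pixel", "shallow_conv"):
        spec = PredictorSpec(kind=kind, seed=5)
        a, b = SoftmaxPixelPredictor(spec), SoftmaxPixelPredictor(spec)
        assert np.array_equal(a.W, b.W)
        feats = a.features(img)
        assert feats.shape[1] == img.size
        probs = a.forward(feats)
        assert probs.shape == (spec.n_classes, img.size)
        assert np.allclose(probs.sum(axis=0), 1.0)
        assert a.predict_mask(img).shape == img.shape


# -- training loop ---------------------------------------------------------------

def test_train_is_deterministic():
    data, _ = generate_dataset(SyntheticConfig(**TINY))
    spec = PredictorSpec(seed=1)
    cfg = StrategyConfig(total_epochs=3, seed=1)
    m1, r1 = train(data, spec, cfg)
    m2, r2 = train(data, spec, cfg)
    assert np.array_equal(m1.W, m2.W)
    assert r1.epoch_losses == r2.epoch_losses


def test_train_reduces_loss_and_learns_something():
    data, _ = generate_dataset(SyntheticConfig(**TINY, boundary_noise_px=0))
    _, record = train(data, PredictorSpec(seed=0),
                      StrategyConfig(total_epochs=12, seed=0), eval_data=data)
    assert record.epoch_losses[-1] < record.epoch_losses[0]
    assert record.metrics.accuracy > 0.6
    assert record.converged


def test_train_with_gd_optimizer_runs():
    data, _ = generate_dataset(SyntheticConfig(**TINY))
    _, record = train(data, PredictorSpec(optimizer="gd", seed=0),
                      StrategyConfig(total_epochs=3, seed=0))
    assert len(record.epoch_losses) == 3


def test_train_records_pixel_filter_statistics():
    data, _ = generate_dataset(SyntheticConfig(**TINY))
    cfg = StrategyConfig(pixel_strategy="bsigma", total_epochs=5,
                         pixel_start_epoch=2, seed=0)
    _, record = train(data, PredictorSpec(seed=0), cfg)
    # filter inactive during the settling epochs, active afterwards
    assert record.discarded_pixels[0] == 0
    assert record.discarded_pixels[1] == 0
    assert all(d > 0 for d in record.discarded_pixels[2:])
    assert record.total_pixels == sum(s.image.size for s in data)


def test_discard_enrichment_definition():
    data, _ = generate_dataset(SyntheticConfig(**TINY))
    cfg = StrategyConfig(pixel_strategy="bsigma", total_epochs=6,
                         pixel_start_epoch=2, seed=0)
    _, record = train(data, PredictorSpec(seed=0), cfg)
    enr = record.discard_enrichment()
    expected = ((record.discarded_corrupted[-1] / record.discarded_pixels[-1])
                / (record.total_corrupted / record.total_pixels))
    assert enr == pytest.approx(expected)


def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError):
        train([], PredictorSpec(), StrategyConfig())


def test_evaluate_predictor_reports_against_clean_masks():
    data, _ = generate_dataset(SyntheticConfig(**TINY))
    model, _ = train(data, PredictorSpec(seed=0),
                     StrategyConfig(total_epochs=8, seed=0))
    report = evaluate_predictor(model, data)
    assert 0.0 <= report.dice <= 1.0
    assert report.n_images == len(data)


# -- ablation -----------------------------------------------------------------

def test_default_grid_strategies_are_valid():
    assert len(DEFAULT_GRID) >= 5
    for image_strategy, smoothing, pixel_strategy in DEFAULT_GRID:
        StrategyConfig(image_strategy=image_strategy, smoothing=smoothing,
                       pixel_strategy=pixel_strategy)


def test_ablate_produces_table():
    data, _ = generate_dataset(SyntheticConfig(**TINY))
    eval_data, _ = generate_dataset(SyntheticConfig(**{**TINY, "seed": 4}))
    grid = [("erm", "none", "all"), ("erm", "none", "bsigma")]
    base = StrategyConfig(total_epochs=2)
    table = ablate(data, eval_data, PredictorSpec(seed=0), grid=grid,
                   base_strategy=base, seeds=[0, 1])
    assert len(table) == 2
    assert "erm+none+all" in table.index
    assert "erm+none+bsigma" in table.index
    dice_cols = [c for c in table.columns if "dice" in c]
    assert dice_cols, table.columns


# -- end-to-end experiment helper ----------------------------------------------

def test_noise_robustness_experiment_returns_expected_fields():
    result = noise_robustness_experiment(seed=0, n_train=6, n_test=4,
                                         size=32, epochs=3)
    for key in ("dice_erm", "dice_full", "dice_gap", "corruption_rate",
                "discard_enrichment"):
        assert key in result
    assert result["corruption_rate"] > 0
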