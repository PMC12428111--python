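# segrank

Rank-based loss aggregation for semantic segmentation under noisy pixel
annotations: average top-k selection over images, sigmoid-smoothed rank
windows, and the "bottom all but σ" pixel filter, with a synthetic data
generator and a training harness to study when each strategy helps.

## The problem

Expert-annotated segmentation masks (medical imaging being the canonical
case) are reliable about *which* structures an image contains but imprecise
about *where* their boundaries lie: annotation tools favor simplified,
smooth outlines, so a band of pixels near every object boundary carries
wrong labels. Training that treats all pixel losses equally — plain
empirical risk minimization (ERM) — spends much of its gradient signal
fitting those mislabeled pixels. Conversely, hard-example mining (top-k
losses) actively seeks them out, since mislabeled pixels are exactly the
ones with the largest losses at convergence.

This package implements a two-level remedy. At the **image level**, losses
are aggregated over a rank window that can emphasize hard images; at the
**pixel level**, the highest-loss pixels of each image — the likely
annotation errors — are discarded before the image loss is formed.

## Core model

Let `ℓ[1] ≤ … ≤ ℓ[N]` be the sorted individual losses. The classic
aggregates are the average `(1/N)·Σᵢ ℓ[i]` (ERM), the maximum `ℓ[N]`, and
the average top-k `(1/k)·Σ_{i=N−k+1}^{N} ℓ[i]`. The windowed *select* loss
generalizes them to an arbitrary contiguous rank window:

    ℓ_select(i0, k) = (1/k) · Σ_{i=i0}^{i0+k−1} ℓ[i]

The hard window indicator is discontinuous in its parameters, which
destabilizes gradient training, so it is replaced by a smooth boxcar built
from two sigmoids `S_α(i, k) = 1 / (1 + e^{−α(i−k)})`:

    ζ_α(i, i0, k) = S_α(i, i0) · S_α(−i, −(i0+k))

with sharpness `α` (the hard indicator is the `α → ∞` limit). For
segmentation the `N = I × P` individual losses (I images × P pixels) nest:
each image's scalar loss is the mean of its **retained** pixel losses, and
the batch objective is the ζ-weighted mean of image losses by epoch rank.
Pixel retention is either *all*, the top 10% hardest (*Tk*), or **bottom
all but σ** (*Bσ*): keep pixels with `ℓ_j ≤ mean + std` of the image's own
loss distribution, discarding the extreme losses that most likely carry
wrong labels.

The per-pixel loss is a cross-entropy / continuous-Dice mixture

    ℓ_j = λ_CE · CE_j + λ_DC · (1 − f·ρ_j),   ρ_cj = ŷ_cj y_cj / (Σ ŷ² + Σ y²)

with defaults `λ = (0.3, 0.7)`; the continuous Dice contribution `ρ` is
defined per pixel and therefore rankable, unlike the hard Dice score
(`f` is 2 by default so a perfect prediction scores 0; `f = 1` gives the
verbatim continuous-Dice form whose per-class ρ-sum is 0.5 at the optimum).

Training schedules follow the reference recipe: `atk` fixes the top window
at 10% of images from the second epoch; `atk_dec` shrinks it linearly from
all images to 5%; smoothing is off (`none`), fixed at α = 20 (`sm`), or
decays 20 → 1 (`sm_inc`). Image ranks are maintained within an epoch by
incremental insertion into a pre-sorted structure, never a full re-sort,
and selection weights are treated as constants in the gradient
(stop-gradient through the sort).

## Worked example

Loss primitives:

```python
from segrank import SelectorConfig, average_top_k, select_average, smoothed_select

losses = [0.2, 0.4, 0.5, 0.9, 3.1]          # one loss per image, any order
print("average top-2 :", average_top_k(losses, k=2))
print("window [2,4]  :", select_average(losses, i0=2, k=3))
sel = SelectorConfig(i0=4, k=2, alpha=20.0)
print("smoothed top-2:", round(smoothed_select(losses, sel), 6))
```

prints

```
average top-2 : 2.0
window [2,4]  : 0.6
smoothed top-2: 1.999966
```

The full mechanism experiment — 60 synthetic 64×64 images, 3 classes, 3 px
boundary displacement on 30% of boundaries, plain mean training vs the
full robust recipe, scored on a clean-labeled test set:

```python
from segrank.harness import noise_robustness_experiment

result = noise_robustness_experiment(seed=5)
print(f"corruption rate of training labels : {result['corruption_rate']:.4f}")
print(f"test Dice, plain mean training     : {result['dice_erm']:.4f}")
print(f"test Dice, AT(down)k + Sm + Bsigma : {result['dice_full']:.4f}")
print(f"corrupted-pixel enrichment in the discarded set: "
      f"{result['discard_enrichment']:.1f}x")
```

prints (≈ 4 s on one CPU)

```
corruption rate of training labels : 0.0151
test Dice, plain mean training     : 0.8525
test Dice, AT(down)k + Sm + Bsigma : 0.8790
corrupted-pixel enrichment in the discarded set: 34.3x
```

Although only 1.5% of training pixels are mislabeled, the Bσ filter's
discarded set is ~34× enriched in them, and test Dice improves.

The same run through the CLI:

```sh
segrank generate --out demo/data --seed 5
# wrote 60 images to demo/data (mean corruption rate 0.0151)
segrank generate --out demo/test --seed 100008

cat > train.yaml <<'YAML'
strategy:
  image_strategy: atk_dec
  smoothing: sm_inc
  pixel_strategy: bsigma
  total_epochs: 30
  seed: 5
predictor:
  seed: 5
YAML

segrank train --config train.yaml --data demo/data --eval-data demo/test
```

which logs the schedule in action and the final clean-mask metrics:

```
epoch   0  loss 0.838933  selected  60  alpha 20.0
epoch   1  loss 0.792294  selected  59  alpha 19.344827586206897
...
epoch  29  loss 0.719243  selected  12  alpha 1.0
{
  "accuracy": 0.9705851236979167,
  "dice": 0.8795708459307698,
  "miou": 0.8040169858139057,
  ...
}
```

`segrank ablate` runs the full strategy grid (`erm/atk/atk_dec ×
none/sm/sm_inc × all/tk/bsigma` presets) over several seeds and writes a
CSV/JSON metrics table; `segrank evaluate` scores a saved model.

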