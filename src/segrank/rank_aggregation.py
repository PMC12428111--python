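"""Rank-based aggregation of individual loss values.

Given a collection of non-negative individual losses ``l_1 … l_N`` sorted in
ascending order (``l[1] <= … <= l[N]``), these primitives compute the classic
aggregates — plain average (empirical risk), maximum, average top-k — and the
windowed "select" generalization: the mean over an arbitrary contiguous rank
window ``[i0, i0 + k - 1]`` (1-based).  The hard window indicator is
discontinuous in the window parameters, which destabilizes gradient training;
a smooth surrogate replaces the indicator with a boxcar built from two
sigmoids of sharpness ``alpha``, giving every rank a weight in (0, 1).

All functions are pure and operate on array-likes; ``incremental_sorted_insert``
maintains the ascending structure across mini-batches so ranks never require a
full re-sort (k insertions into a sorted array of size N, O(k*N)).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SelectorConfig",
    "average_loss",
    "maximum_loss",
    "average_top_k",
    "select_average",
    "sigmoid_indicator",
    "boxcar_selector",
    "smoothed_select",
    "incremental_sorted_insert",
]

#: normalization modes for the smoothed windowed mean
NORMALIZATIONS = ("paper_N", "paper_k", "effective_weight")


@dataclass(frozen=True)
class SelectorConfig:
    """Rank-window selector: window start ``i0`` (1-based), width ``k``,
    sigmoid sharpness ``alpha``, and the normalizer of the weighted sum.

    ``normalization`` is one of:

    - ``"effective_weight"`` (default): divide by the total selector weight,
      so the result is a weighted mean that converges to the hard windowed
      mean as ``alpha -> inf``;
    - ``"paper_k"``: divide by the window width ``k``;
    - ``"paper_N"``: divide by the number of losses ``N``.
    """

    i0: int
    k: int
    alpha: float
    normalization: str = "effective_weight"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"window width k must be >= 1, got {self.k}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )

    def validate_for(self, n: int) -> None:
        """Check the window fits inside ranks ``1 … n``."""
        if self.i0 < 1 or self.i0 + self.k - 1 > n:
            raise ValueError(
                f"window [{self.i0}, {self.i0 + self.k - 1}] out of range "
                f"for {n} losses"
            )


def _as_loss_vector(values) -> np.ndarray:
    """Validate and return a 1-D float array of individual losses."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("loss vector must contain at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("loss values must be finite")
    if np.any(arr < 0):
        raise ValueError("loss values must be non-negative")
    return arr


def average_loss(values) -> float:
    """Mean of all individual losses (the empirical-risk objective)."""
    return float(np.mean(_as_loss_vector(values)))


def maximum_loss(values) -> float:
    """Largest individual loss, ``l[N]``; an upper bound on the average."""
    return float(np.max(_as_loss_vector(values)))


def average_top_k(values, k: int) -> float:
    """Mean of the ``k`` largest losses.

    ``k = N`` recovers the plain average; ``k = 1`` recovers the maximum.
    The result is non-increasing in ``k``.
    """
    arr = _as_loss_vector(values)
    if not 1 <= k <= arr.size:
        raise ValueError(f"k must be in [1, {arr.size}], got {k}")
    # partition is O(N); full sort is unnecessary for a single query
    top = np.partition(arr, arr.size - k)[arr.size - k:]
    return float(np.mean(top))


def select_average(values, i0: int, k: int) -> float:
    """Mean of losses with ascending ranks in the window ``[i0, i0+k-1]``.

    With ``i0 = N - k + 1`` this is the average top-k; with ``i0 = 1`` it is
    the average bottom-k.
    """
    arr = _as_loss_vector(values)
    n = arr.size
    if k < 1 or i0 < 1 or i0 + k - 1 > n:
        raise ValueError(f"window [{i0}, {i0 + k - 1}] out of range for N={n}")
    srt = np.sort(arr, kind="stable")
    return float(np.mean(srt[i0 - 1: i0 + k - 1]))


def sigmoid_indicator(i, k, alpha: float):
    """Smooth approximation ``S_alpha(i, k) = 1 / (1 + exp(-alpha (i - k)))``
    of the step indicator ``I(i >= k)``.

    Strictly increasing in ``i`` and equal to 0.5 at ``i = k``; approaches the
    hard indicator pointwise as ``alpha -> inf``.  Computed in a branch-safe
    form so large ``|alpha * (i - k)|`` saturates to 0 or 1 without overflow.
    Accepts scalars or arrays.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    z = alpha * (np.asarray(i, dtype=float) - np.asarray(k, dtype=float))
    # scipy.special.expit is equivalent; inlined to keep this module pure numpy
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if np.ndim(i) == 0 and np.ndim(k) == 0:
        return float(out)
    return out


def boxcar_selector(i, i0, k, alpha: float):
    """Smooth boxcar ``zeta_alpha(i, i0, k) = S_alpha(i, i0) * S_alpha(-i, -(i0+k))``,
    approximating the window indicator ``I(i0 <= i < i0 + k)``.

    The rising edge sits at ``i0`` and the falling edge at ``i0 + k``; both
    edges evaluate to ~0.5 when the window is wide relative to ``1/alpha``.
    """
    if np.any(np.asarray(k, dtype=float) <= 0):
        raise ValueError("window width k must be > 0")
    rise = sigmoid_indicator(i, i0, alpha)
    fall = sigmoid_indicator(np.negative(i), np.negative(np.asarray(i0) + np.asarray(k)), alpha)
    return rise * fall


def smoothed_select(values, sel: SelectorConfig) -> float:
    """Sigmoid-smoothed windowed mean of the sorted losses.

    Each ascending rank ``i`` receives weight ``zeta_alpha(i, i0, k)``; the
    weighted sum is divided by the normalizer chosen in ``sel``:  the total
    selector weight (default, giving a weighted mean that tends to
    :func:`select_average` as ``alpha -> inf``), the window width ``k``, or
    the number of losses ``N``.
    """
    arr = _as_loss_vector(values)
    n = arr.size
    sel.validate_for(n)
    srt = np.sort(arr, kind="stable")
    ranks = np.arange(1, n + 1, dtype=float)
    # the window indicator is I(i0 <= i <= i0+k-1) on integer ranks; center the
    # smooth edges half a rank outside so integer ranks sit symmetrically
    weights = boxcar_selector(ranks, sel.i0 - 0.5, float(sel.k), sel.alpha)
    total = float(np.sum(weights * srt))
    if sel.normalization == "paper_N":
        return total / n
    if sel.normalization == "paper_k":
        return total / sel.k
    wsum = float(np.sum(weights))
    if wsum <= 1e-300:
        raise FloatingPointError("effective selector weight is numerically zero")
    return total / wsum


def incremental_sorted_insert(
    sorted_state: Sequence[float], batch: Sequence[float]
) -> tuple[list[float], list[int]]:
    """Insert a batch of values into an ascending sequence, one by one.

    Returns the merged ascending list and the 1-based rank of each batch item
    in the merged sequence (in batch order).  Ties insert after existing equal
    values, so earlier-seen values keep lower ranks.  Equivalent to a full
    stable sort of the union but costs O(len(batch) * N).
    """
    state = [float(v) for v in sorted_state]
    items = [float(v) for v in batch]
    if not all(np.isfinite(v) for v in state + items):
        raise ValueError("values must be finite")
    tags: list[int | None] = [None] * len(state)
    for t, v in enumerate(items):
        idx = bisect.bisect_right(state, v)
        state.insert(idx, v)
        tags.insert(idx, t)
    ranks = [0] * len(items)
    for pos, t in enumerate(tags):
        if t is not None:
            ranks[t] = pos + 1
    return state, ranks
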