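"""Unit and property tests for the rank-aggregation primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from segrank.rank_aggregation import (
    SelectorConfig,
    average_loss,
    average_top_k,
    boxcar_selector,
    incremental_sorted_insert,
    maximum_loss,
    select_average,
    sigmoid_indicator,
    smoothed_select,
)

loss_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False, allow_infinity=False),
    min_size=1,
    max_size=64,
)


# -- classic aggregates -----------------------------------------------------

def test_average_and_maximum_basic():
    assert average_loss([1, 2, 3, 4]) == pytest.approx(2.5)
    assert maximum_loss([1, 2, 3, 4]) == 4.0


@given(loss_vectors)
def test_top_k_interpolates_between_mean_and_max(values):
    n = len(values)
    assert average_top_k(values, n) == pytest.approx(average_loss(values), rel=1e-12)
    assert average_top_k(values, 1) == pytest.approx(maximum_loss(values), rel=1e-12)


@given(loss_vectors)
def test_top_k_monotone_non_increasing_in_k(values):
    n = len(values)
    vals = [average_top_k(values, k) for k in range(1, n + 1)]
    for a, b in zip(vals, vals[1:]):
        assert a >= b - 1e-9


@given(loss_vectors)
def test_aggregate_ordering(values):
    n = len(values)
    for k in range(1, n + 1):
        atk = average_top_k(values, k)
        assert maximum_loss(values) >= atk - 1e-9
        assert atk >= average_loss(values) - 1e-9


def test_loss_vector_validation():
    for bad in ([], [1.0, -0.5], [np.nan], [np.inf]):
        with pytest.raises(ValueError):
            average_loss(bad)


# -- windowed select --------------------------------------------------------

def test_select_average_examples():
    assert select_average([1, 2, 3, 4, 5], i0=2, k=2) == pytest.approx(2.5)
    assert select_average([1, 2, 3, 4, 5], i0=1, k=5) == pytest.approx(3.0)


@given(loss_vectors, st.data())
def test_select_average_matches_sort_slice_oracle(values, data):
    n = len(values)
    k = data.draw(st.integers(1, n))
    i0 = data.draw(st.integers(1, n - k + 1))
    expected = float(np.mean(np.sort(values)[i0 - 1: i0 + k - 1]))
    assert select_average(values, i0, k) == pytest.approx(expected, rel=1e-12)


@given(loss_vectors, st.data())
def test_select_top_window_is_average_top_k(values, data):
    n = len(values)
    k = data.draw(st.integers(1, n))
    assert select_average(values, n - k + 1, k) == pytest.approx(
        average_top_k(values, k), rel=1e-12
    )


def test_select_average_window_validation():
    with pytest.raises(ValueError):
        select_average([1, 2, 3], i0=3, k=2)
    with pytest.raises(ValueError):
        select_average([1, 2, 3], i0=0, k=2)


# -- smooth selector --------------------------------------------------------

def test_sigmoid_indicator_midpoint_and_monotonicity():
    assert sigmoid_indicator(5.0, 5.0, alpha=3.0) == pytest.approx(0.5)
    grid = np.linspace(-10, 10, 101)
    out = sigmoid_indicator(grid, 0.0, alpha=2.0)
    assert np.all(np.diff(out) > 0)
    assert np.all((out > 0) & (out < 1))


def test_sigmoid_indicator_saturates_without_overflow():
    assert sigmoid_indicator(1e6, 0.0, alpha=100.0) == pytest.approx(1.0)
    assert sigmoid_indicator(-1e6, 0.0, alpha=100.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        sigmoid_indicator(0.0, 0.0, alpha=0.0)


def test_boxcar_approximates_window_indicator():
    i0, k, alpha = 10.0, 5.0, 20.0
    ranks = np.arange(1, 31, dtype=float)
    hard = ((ranks > i0) & (ranks < i0 + k)).astype(float)
    inner = (np.abs(ranks - i0) >= 1) & (np.abs(ranks - (i0 + k)) >= 1)
    zeta = boxcar_selector(ranks, i0, k, alpha)
    assert np.max(np.abs(zeta[inner] - hard[inner])) < 1e-8
    # both edges sit at ~0.5
    assert boxcar_selector(i0, i0, k, alpha) == pytest.approx(0.5, abs=1e-6)
    assert boxcar_selector(i0 + k, i0, k, alpha) == pytest.approx(0.5, abs=1e-6)


def test_smoothed_select_examples_from_hard_limits():
    sel = SelectorConfig(i0=4, k=2, alpha=50.0)
    assert smoothed_select([1, 2, 3, 4, 5], sel) == pytest.approx(4.5, abs=1e-6)
    const = [3.7] * 8
    sel_any = SelectorConfig(i0=3, k=4, alpha=50.0)
    assert smoothed_select(const, sel_any) == pytest.approx(3.7, rel=1e-12)
    sel_full = SelectorConfig(i0=1, k=5, alpha=50.0, normalization="paper_N")
    assert smoothed_select([1, 2, 3, 4, 5], sel_full) == pytest.approx(
        average_loss([1, 2, 3, 4, 5]), abs=1e-6
    )


@given(loss_vectors, st.data())
def test_smoothed_select_converges_to_hard_window(values, data):
    n = len(values)
    k = data.draw(st.integers(1, n))
    i0 = data.draw(st.integers(1, n - k + 1))
    sel = SelectorConfig(i0=i0, k=k, alpha=200.0)
    hard = select_average(values, i0, k)
    assert smoothed_select(values, sel) == pytest.approx(hard, rel=1e-6, abs=1e-6)


def test_smoothed_select_normalization_relationships():
    values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    i0, k, alpha = 4, 3, 30.0
    by_k = smoothed_select(values, SelectorConfig(i0, k, alpha, "paper_k"))
    by_n = smoothed_select(values, SelectorConfig(i0, k, alpha, "paper_N"))
    # same weighted sum, different normalizer
    assert by_k * k == pytest.approx(by_n * len(values), rel=1e-12)


def test_selector_config_validation():
    with pytest.raises(ValueError):
        SelectorConfig(i0=1, k=0, alpha=1.0)
    with pytest.raises(ValueError):
        SelectorConfig(i0=1, k=1, alpha=-1.0)
    with pytest.raises(ValueError):
        SelectorConfig(i0=1, k=1, alpha=1.0, normalization="bogus")
    with pytest.raises(ValueError):
        SelectorConfig(i0=5, k=3, alpha=1.0).validate_for(6)


# -- incremental insertion --------------------------------------------------

def test_incremental_insert_examples():
    merged, ranks = incremental_sorted_insert([1, 3, 5], [2, 4])
    assert merged == [1, 2, 3, 4, 5]
    assert ranks == [2, 4]
    merged, _ = incremental_sorted_insert([], [3, 1, 2])
    assert merged == [1, 2, 3]


def test_incremental_insert_tie_rule():
    # ties insert after existing equal values
    merged, ranks = incremental_sorted_insert([2.0, 2.0], [2.0])
    assert merged == [2.0, 2.0, 2.0]
    assert ranks == [3]


def test_incremental_insert_rejects_non_finite():
    with pytest.raises(ValueError):
        incremental_sorted_insert([1.0], [np.nan])
    with pytest.raises(ValueError):
        incremental_sorted_insert([np.inf], [1.0])


@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=40),
       st.integers(1, 7))
def test_incremental_insert_equals_full_sort(values, batch_size):
    state: list[float] = []
    for start in range(0, len(values), batch_size):
        state, ranks = incremental_sorted_insert(state, values[start:start + batch_size])
        assert all(1 <= r <= len(state) for r in ranks)
    assert state == sorted(float(v) for v in values)


def test_incremental_insert_random_oracle():
    rng = np.random.default_rng(7)
    values = rng.uniform(0, 10, size=1000)
    state: list[float] = []
    pos = 0
    while pos < values.size:
        b = int(rng.integers(1, 17))
        state, _ = incremental_sorted_insert(state, values[pos:pos + b])
        pos += b
    assert np.allclose(state, np.sort(values))
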