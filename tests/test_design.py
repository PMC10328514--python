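"""Toeplitz design construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valuecode.design import (KernelWindow, Segments, assemble_full_design,
                              assemble_restricted_design, scaled_cue_design,
                              toeplitz_block)
from valuecode.task import EventLog, TaskConfig, generate_task


def _segments(n_trials=4, gap=10.0, window=(-1.0, 6.5)):
    return Segments(onsets=15.0 + gap * np.arange(n_trials), window=window)


def test_single_event_stripe():
    """One event, support 0-0.5 s: 5 columns, one 1 each, consecutive rows."""
    seg = _segments(1)
    block = toeplitz_block(np.array([15.0]), KernelWindow("k", 0.0, 0.5), seg)
    dense = block.toarray()
    assert dense.shape == (75, 5)
    assert (dense.sum(axis=0) == 1).all()
    rows = dense.argmax(axis=0)
    assert np.array_equal(np.diff(rows), np.ones(4))
    assert rows[0] == 10  # event at t=0 lands 1 s (10 bins) into the segment


def test_two_events_linear_superposition():
    seg = _segments(2)
    w = KernelWindow("k", 0.0, 0.5)
    both = toeplitz_block(np.array([15.0, 25.0]), w, seg).toarray()
    one = toeplitz_block(np.array([15.0]), w, seg).toarray()
    two = toeplitz_block(np.array([25.0]), w, seg).toarray()
    assert np.array_equal(both, one + two)


def test_stripe_truncated_at_segment_boundary():
    seg = _segments(1)
    w = KernelWindow("k", 0.0, 5.0)
    block = toeplitz_block(np.array([15.0 + 4.0]), w, seg).toarray()
    # event 4 s into the 6.5 s window: only 2.5 s of support fits
    assert block.sum() == 25


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_toeplitz_convolution_oracle(seed):
    """P @ k equals direct convolution of the event train with k."""
    rng = np.random.default_rng(seed)
    seg = Segments(onsets=np.array([20.0]), window=(-1.0, 6.5))
    n_lags = int(rng.integers(1, 30))
    t_min = 0.1 * int(rng.integers(-5, 5))
    w = KernelWindow("k", t_min, t_min + 0.1 * n_lags)
    n_ev = int(rng.integers(0, 8))
    ev = np.sort(rng.uniform(19.0, 25.5, n_ev))
    k = rng.normal(size=n_lags)
    P = toeplitz_block(ev, w, seg).toarray()
    got = P @ k
    # oracle: place k at each event's bin + lag offset
    expect = np.zeros(75)
    for e in ev:
        b = int(np.floor((e - 19.0) / 0.1 + 1e-9))
        for j in range(n_lags):
            r = b + w.lag0 + j
            if 0 <= r < 75:
                expect[r] += k[j]
    assert np.allclose(got, expect, atol=1e-12)


@pytest.fixture(scope="module")
def session72():
    return generate_task(TaskConfig(trials_per_block=12, n_blocks=6, seed=31))


def test_full_design_column_count(session72):
    """6*50 cue + 6 lick + 23 bout + 6 rate + 40 reward + 6 block = 381."""
    trials, events = session72
    d = assemble_full_design(trials, events)
    assert d.n_cols == 381
    assert d.n_rows == len(trials) * 75
    sizes = {g: v.size for g, v in d.column_groups.items()}
    assert sizes == {"cues": 300, "licks": 35, "reward": 40, "const": 6}


def test_no_licks_zero_lick_columns(session72):
    trials, _ = session72
    empty = EventLog(lick_times=np.array([]), bout_starts=np.array([]),
                     reward_times=np.array([]),
                     reward_consumption_onsets=np.array([]))
    d = assemble_full_design(trials, empty)
    lick_cols = d.X[:, d.column_groups["licks"]]
    assert lick_cols.nnz == 0


def test_block_constants_partition_rows(session72):
    trials, events = session72
    d = assemble_full_design(trials, events)
    const = d.X[:, d.column_groups["const"]].toarray()
    assert np.array_equal(const.sum(axis=1), np.ones(d.n_rows))
    assert set(np.unique(const)) == {0.0, 1.0}


def test_restricted_design_shape_and_groups(session72):
    trials, events = session72
    d = assemble_restricted_design(trials, events)
    assert d.segments.n_bins_per_trial == 35  # (2.5 - (-1)) / 0.1
    assert d.n_rows == len(trials) * 35
    assert "reward" not in d.column_groups


def test_restricted_is_submatrix_of_full_for_shared_predictors(session72):
    """Cue-kernel columns of the restricted design match the corresponding
    rows/columns of the full design."""
    trials, events = session72
    full = assemble_full_design(trials, events)
    rest = assemble_restricted_design(trials, events)
    # map restricted rows into full rows: both windows start at -1 s
    n = len(trials)
    full_rows = (np.arange(n)[:, None] * 75 + np.arange(35)[None, :]).ravel()
    # restricted cue kernels are the first 25 lags of each full cue kernel
    for c in range(6):
        fcols = full.column_groups["cues"][c * 50: c * 50 + 25]
        rcols = rest.column_groups["cues"][c * 25: (c + 1) * 25]
        a = full.X[full_rows][:, fcols].toarray()
        b = rest.X[:, rcols].toarray()
        assert np.array_equal(a, b)


def test_scaled_design_constant_one_equals_plain_block(session72):
    trials, events = session72
    d = scaled_cue_design(trials, np.ones(len(trials)))
    seg = d.segments
    plain = toeplitz_block(trials.cue_onset.to_numpy(),
                           KernelWindow("cue", 0.0, 2.5), seg).toarray()
    assert np.array_equal(d.X[:, d.column_groups["cues"]].toarray(), plain)


def test_scaled_design_zero_value_trials_blank(session72):
    trials, _ = session72
    v = trials.cue_value.to_numpy()
    d = scaled_cue_design(trials, v)
    X = d.X[:, d.column_groups["cues"]].toarray()
    w = d.segments.n_bins_per_trial
    for t in np.flatnonzero(v == 0):
        assert not X[t * w:(t + 1) * w].any()
    for t in np.flatnonzero(v == 1.0)[:3]:
        assert X[t * w:(t + 1) * w].max() == 1.0


def test_scaled_design_rejects_negative_values(session72):
    trials, _ = session72
    with pytest.raises(ValueError):
        scaled_cue_design(trials, np.full(len(trials), -0.1))


def test_scaled_design_forward_peak_ratio(session72):
    """P @ k under ranked values gives exactly 2x CS+ vs CS50 peaks."""
    trials, _ = session72
    d = scaled_cue_design(trials, trials.cue_value.to_numpy())
    k = np.sin(np.linspace(0, np.pi, 25))
    rate = d.X[:, d.column_groups["cues"]] @ k
    w = d.segments.n_bins_per_trial
    peaks = rate.reshape(len(trials), w).max(axis=1)
    plus = peaks[(trials.reward_prob == 1.0).to_numpy()]
    fifty = peaks[(trials.reward_prob == 0.5).to_numpy()]
    assert np.allclose(plus, 2 * fifty)


def test_missing_block_labels_rejected(session72):
    trials, events = session72
    with pytest.raises(ValueError):
        assemble_full_design(trials.drop(columns=["block_index"]), events)
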