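"""Binning, smoothing, PSTH construction, and z-scoring."""

import numpy as np
import pandas as pd
import pytest

import valuecode.psth as psth
from valuecode.psth import (BinnedActivity, baseline_stats,
                            bin_and_smooth_spikes, classify_polarity,
                            half_normal_filter, lick_psth, make_psth, rebin,
                            zscore_to_baseline)
from valuecode.task import EventLog, TaskConfig, generate_task


def _trials(n=20, gap=10.0, t0=15.0):
    onsets = t0 + gap * np.arange(n)
    return pd.DataFrame({
        "trial_index": np.arange(n),
        "cue_id": ["A+", "A50", "A-", "B+"] * (n // 4),
        "cue_index": [0, 1, 2, 3] * (n // 4),
        "cue_onset": onsets,
        "block_index": 1 + (np.arange(n) >= n // 2).astype(int),
    })


def test_filter_closed_form():
    """w(k) ~ exp(-(k*dt)^2 / 2 sigma^2), causal, normalized."""
    w = half_normal_filter(0.3, 50, 0.02)
    assert w.shape == (50,)
    assert np.isclose(w.sum(), 1.0)
    assert (np.diff(w) <= 0).all()  # maximum at lag 0
    expected_ratio = np.exp(-((49 * 0.02) ** 2) / (2 * 0.3**2)) / 1.0
    assert np.isclose(w[49] / w[0], expected_ratio)


def test_empty_spike_train_all_zero():
    act = bin_and_smooth_spikes([np.array([])], session_end=10.0)
    assert not act.values.any()


def test_single_spike_causal_peak():
    """Causal filter: output peaks at the spike's own bin, zero before."""
    act = bin_and_smooth_spikes([np.array([5.0])], session_end=10.0)
    v = act.values[:, 0]
    spike_bin = int(5.0 / act.bin_width)
    assert v.argmax() == spike_bin
    assert not v[:spike_bin].any()


def test_unsorted_spikes_rejected():
    with pytest.raises(ValueError):
        bin_and_smooth_spikes([np.array([2.0, 1.0])], session_end=5.0)


def test_smoothing_conserves_mass():
    """Total count mass survives smoothing up to the filter's edge tail."""
    rng = np.random.default_rng(0)
    spikes = np.sort(rng.uniform(0, 80, 500))
    act = bin_and_smooth_spikes([spikes], session_end=100.0)
    mass = act.values[:, 0].sum() * act.bin_width
    assert np.isclose(mass, 500, rtol=1e-6)


def test_constant_rate_gives_flat_psth():
    trials = _trials()
    T = int(250 / 0.02)
    act = BinnedActivity(values=np.full((T, 1), 4.0), bin_width=0.02)
    p = make_psth(act, trials, window=(-1.0, 6.5))
    assert np.allclose(p.values, 4.0)


def test_psth_all_is_weighted_mean_of_even_odd():
    trials, events = generate_task(TaskConfig(trials_per_block=12, n_blocks=6,
                                              seed=21))
    rng = np.random.default_rng(1)
    T = int((trials.cue_onset.iloc[-1] + 10) / 0.02)
    act = BinnedActivity(values=rng.normal(size=(T, 2)), bin_width=0.02)
    p_all = make_psth(act, trials)
    p_even = make_psth(act, trials, trial_filter="even")
    p_odd = make_psth(act, trials, trial_filter="odd")
    for ci, cue in enumerate(p_all.cue_labels):
        n_even = ((trials.cue_id == cue) & (trials.trial_index % 2 == 0)).sum()
        n_odd = ((trials.cue_id == cue) & (trials.trial_index % 2 == 1)).sum()
        blend = (n_even * p_even.values[:, ci] + n_odd * p_odd.values[:, ci]) \
            / (n_even + n_odd)
        assert np.allclose(blend, p_all.values[:, ci], atol=1e-10)


def test_zscore_baseline_statistics():
    """Gaussian baseline z-scores to mean ~0, SD ~1 at 300 trials."""
    trials = _trials(n=300, gap=10.0)
    rng = np.random.default_rng(2)
    T = int((trials.cue_onset.iloc[-1] + 10) / 0.02)
    act = BinnedActivity(values=3.0 + 2.0 * rng.normal(size=(T, 1)),
                         bin_width=0.02)
    z = zscore_to_baseline(act, trials=trials)
    mu, sd = baseline_stats(z, trials)
    assert abs(mu[0]) < 0.05
    assert 0.9 < sd[0] < 1.1


def test_zscore_constant_neuron_flagged():
    trials = _trials()
    T = int(250 / 0.02)
    act = BinnedActivity(values=np.full((T, 1), 2.0), bin_width=0.02)
    z = zscore_to_baseline(act, trials=trials)
    assert z.flagged[0]
    assert not z.values.any()


def test_zscore_twice_rejected():
    trials = _trials()
    act = BinnedActivity(values=np.random.default_rng(3).normal(
        size=(int(250 / 0.02), 1)), bin_width=0.02)
    z = zscore_to_baseline(act, trials=trials)
    with pytest.raises(ValueError):
        zscore_to_baseline(z, trials=trials)


def test_lick_psth_empty_and_value_ordered():
    trials, events = generate_task(TaskConfig(trials_per_block=12, n_blocks=6,
                                              seed=22))
    empty = EventLog(lick_times=np.array([]), bout_starts=np.array([]),
                     reward_times=np.array([]),
                     reward_consumption_onsets=np.array([]))
    p0 = lick_psth(empty, trials)
    assert not p0.values.any()
    p = lick_psth(events, trials, window=(-1.0, 2.5))
    t = p.bin_times()
    sel = (t >= 0) & (t < 2.5)
    plus = p.values[0, p.cue_labels.index("A+"), sel].mean()
    minus = p.values[0, p.cue_labels.index("A-"), sel].mean()
    assert plus > minus


def test_polarity_classification():
    trials = _trials()
    n_bins = 75
    vals = np.zeros((3, 4, n_bins))
    t = -1.0 + (np.arange(n_bins) + 0.5) * 0.1
    resp = (t >= 0.2) & (t < 1.0)
    vals[0, 0, resp] = 3.0     # excited
    vals[1, 0, resp] = -3.0    # suppressed
    p = psth.PsthTensor(values=vals, window=(-1.0, 6.5), bin_width=0.1,
                        cue_labels=("A+", "A50", "A-", "B+"),
                        trial_sets="even", zscored=True)
    pol = classify_polarity(p)
    assert list(pol) == ["above", "below", "above"]  # tie -> above


def test_rebin_preserves_rate_units():
    act = BinnedActivity(values=np.full((100, 1), 7.0), bin_width=0.02)
    coarse = rebin(act, 0.1)
    assert coarse.values.shape == (20, 1)
    assert np.allclose(coarse.values, 7.0)


def test_forward_model_psth_recovers_cue_kernel(small_session, small_prepared):
    """The CS+ PSTH of a generated value neuron matches the injected
    kernel shape within Monte-Carlo tolerance."""
    sess, prep = small_session, small_prepared
    value_neurons = [i for i, l in enumerate(sess.truth.labels())
                     if l == "value"]
    act_raw = psth.bin_and_smooth_spikes(sess.spikes, sess.session_end)
    p = make_psth(act_raw, sess.trials, window=(0.0, 2.5))
    # expected trace: injected kernel passed through the same causal filter
    w = half_normal_filter(0.3, 50, 0.02)
    rs = []
    for n in value_neurons:
        k = sess.truth.cue_kernel(n, dt=0.02)
        k_sm = np.convolve(k, w)[: k.size]
        k_sm = k_sm[: 25 * 5].reshape(25, 5).mean(axis=1)  # to 0.1 s bins
        # average A+ and B+ trials (identical expected response)
        trace = (p.values[n, p.cue_labels.index("A+"), :]
                 + p.values[n, p.cue_labels.index("B+"), :]) / 2
        rs.append(np.corrcoef(trace - trace.mean(), k_sm - k_sm.mean())[0, 1])
    assert np.mean(rs) > 0.7
    assert min(rs) > 0.5
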