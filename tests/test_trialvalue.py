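"""Trial-value lick model and neural history model."""

import numpy as np
import pandas as pd
import pytest

import valuecode as vc
from valuecode.task import CUE_LABELS, EventLog, TaskConfig, generate_task
from valuecode.trialvalue import (_history_regressors,
                                  anticipatory_lick_counts,
                                  fit_history_model, fit_trial_value_model,
                                  flag_history_neurons)
from valuecode.tuning import ScaledCueFitter


def _deterministic_session(seed=51):
    """Licks placed so every trial's anticipatory count is 10 * cue value."""
    trials, _ = generate_task(TaskConfig(trials_per_block=12, n_blocks=6,
                                         seed=seed))
    licks = []
    for _, row in trials.iterrows():
        n = int(round(10 * row.cue_value))
        licks.extend(row.cue_onset + 0.1 + 0.2 * np.arange(n))
    licks = np.sort(np.asarray(licks))
    events = EventLog(lick_times=licks, bout_starts=licks[:1],
                      reward_times=np.array([]),
                      reward_consumption_onsets=np.array([]))
    return trials, events


def test_anticipatory_counts_window():
    trials, events = _deterministic_session()
    counts = anticipatory_lick_counts(trials, events)
    assert np.array_equal(counts, 10 * trials.cue_value.to_numpy())


def test_noiseless_least_squares_recovers_cue_pattern():
    """Deterministic licking (10 * value) recovers the 1:0.5:0 pattern
    exactly after session-max normalization."""
    fit = fit_trial_value_model([_deterministic_session()])
    beta = fit.beta_cue
    by_cue = {c: beta[f"cue:{c}"] for c in CUE_LABELS}
    assert np.allclose([by_cue["A+"], by_cue["B+"]], 1.0, atol=1e-8)
    assert np.allclose([by_cue["A50"], by_cue["B50"]], 0.5, atol=1e-8)
    assert np.allclose([by_cue["A-"], by_cue["B-"]], 0.0, atol=1e-8)
    assert np.allclose(np.concatenate([fit.beta_hist_overall,
                                       fit.beta_hist_cue]), 0.0, atol=1e-8)
    v = fit.per_trial_value[0]
    trials, _ = _deterministic_session()
    assert np.allclose(v, trials.cue_value, atol=1e-8)


def test_history_regressors_zero_padded():
    trials = pd.DataFrame({
        "cue_index": [0, 1, 0, 0],
        "rewarded": [True, False, True, False],
    })
    overall, same = _history_regressors(trials, depth=3)
    assert overall.shape == (4, 3)
    assert np.array_equal(overall[0], [0, 0, 0])          # no predecessors
    assert np.array_equal(overall[1], [1, 0, 0])
    assert np.array_equal(overall[3], [1, 0, 1])
    assert np.array_equal(same[2], [1, 0, 0])             # same-cue lag 1
    assert np.array_equal(same[3], [1, 1, 0])


def test_history_coefficients_recover_injected_decay():
    """Same-cue history in the generator shows up as positive, lag-1-largest
    same-cue coefficients."""
    sessions = [generate_task(TaskConfig(seed=s, history_weight=0.6))
                for s in (61, 62, 63)]
    fit = fit_trial_value_model(sessions)
    bc = fit.beta_hist_cue.to_numpy()
    assert bc[0] > 0
    assert bc[0] == max(bc)


def test_null_history_coefficients_near_zero():
    """With history weight 0, the same-cue history coefficients stay within
    their confidence intervals of 0."""
    sessions = [generate_task(TaskConfig(seed=s, history_weight=0.0))
                for s in (71, 72, 73)]
    fit = fit_trial_value_model(sessions)
    ci = fit.result.conf_int()
    names = fit.design_columns
    cover = [ci[i][0] <= 0 <= ci[i][1]
             for i, nm in enumerate(names) if nm.startswith("hist_cue")]
    assert np.mean(cover) >= 0.8


def test_value_ordering_invariant():
    trials, events = generate_task(TaskConfig(seed=81, history_weight=0.4))
    fit = fit_trial_value_model([(trials, events)])
    v = fit.per_trial_value[0]
    means = pd.Series(v).groupby(trials.reward_prob.to_numpy()).mean()
    assert means[1.0] > means[0.5] > means[0.0]


def test_residuals_orthogonal_to_regressors():
    trials, events = generate_task(TaskConfig(seed=82, history_weight=0.4))
    fit = fit_trial_value_model([(trials, events)])
    X = fit.result.model.exog
    resid = fit.result.resid
    assert np.allclose(X.T @ resid, 0.0, atol=1e-8)


@pytest.fixture(scope="module")
def history_setup():
    # full-length session: within-cue value variation needs ~50 trials/cue
    cfg = TaskConfig(seed=91, history_weight=0.5)
    truth = vc.make_population(n_value=3, n_history=3, seed=92)
    sess = vc.simulate_session(cfg, truth)
    prep = vc.prepare_session(sess)
    fit = fit_trial_value_model([(sess.trials, sess.events)])
    fitter = ScaledCueFitter(prep.trials, prep.F_restricted)
    return sess, prep, fitter, fit.per_trial_value[0]


def test_constant_values_reduce_to_ranked_model(history_setup):
    """v_t constant per cue (1, 0.5, 0) builds the identical design, so the
    history fit equals the ranked-model fit exactly."""
    sess, prep, fitter, _ = history_setup
    v_const = sess.trials.cue_value.to_numpy()
    cols = np.arange(3)
    hist = fit_history_model(fitter, v_const, cols)
    ranked = fitter.score_model((1.0, 0.5, 0.0, 1.0, 0.5, 0.0), cols)
    assert np.allclose(hist, ranked)


def test_within_cue_shuffle_preserves_cue_means(history_setup):
    sess, prep, fitter, v_t = history_setup
    rng = np.random.default_rng(0)
    cue = fitter.cue_index
    v = np.clip(v_t, 0, None)
    v_shuf = v.copy()
    for c in np.unique(cue):
        sel = np.flatnonzero(cue == c)
        v_shuf[sel] = v[sel[rng.permutation(sel.size)]]
    for c in np.unique(cue):
        sel = cue == c
        assert np.isclose(v[sel].mean(), v_shuf[sel].mean())


def test_history_neurons_flagged_static_not(history_setup):
    sess, prep, fitter, v_t = history_setup
    labels = np.array(sess.truth.labels())
    cols = np.arange(6)
    res = flag_history_neurons(fitter, v_t, cols, n_null=100, seed=1)
    hist_rows = res[labels[cols] == "history"]
    static_rows = res[labels[cols] == "value"]
    assert hist_rows.history.mean() >= 2 / 3
    assert static_rows.history.mean() <= 1 / 3


def test_missing_trial_values_rejected(history_setup):
    _, prep, fitter, v_t = history_setup
    with pytest.raises(ValueError):
        fit_history_model(fitter, v_t[:-1], np.arange(2))
    with pytest.raises(ValueError):
        fit_history_model(fitter, np.full_like(v_t, np.nan), np.arange(2))
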