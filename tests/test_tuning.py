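"""Cue-tuning model enumeration, categorization, and selection."""

from itertools import combinations, permutations

import numpy as np
import pytest

import valuecode as vc
from valuecode.task import TaskConfig
from valuecode import tuning
from valuecode.tuning import (ScaledCueFitter, correlate_with_ranked,
                              enumerate_models, fit_all_models,
                              models_table, select_best_model)


@pytest.fixture(scope="module")
def models():
    return enumerate_models()


def test_enumeration_counts(models):
    """90 graded permutations + 63 binary patterns = 153 distinct models."""
    assert len(models) == 153
    graded = [m for m in models if m.family == "graded_permutation"]
    binary = [m for m in models if m.family == "binary_selective"]
    assert len(graded) == 90   # 6! / (2! 2! 2!)
    assert len(binary) == 63   # sum_k C(6, k)
    assert len({m.values for m in models}) == 153
    assert sum(m.category != "ranked_value" for m in models) == 152


def test_enumeration_matches_brute_force(models):
    """Independent enumeration via itertools set-dedup."""
    expected = set(permutations((1.0, 1.0, 0.5, 0.5, 0.0, 0.0)))
    for k in range(1, 7):
        for ones in combinations(range(6), k):
            expected.add(tuple(1.0 if i in ones else 0.0 for i in range(6)))
    assert {m.values for m in models} == expected


def test_enumeration_order_stable(models):
    """Ranked model first, then lexicographic; idempotent across calls."""
    assert models[0].values == (1.0, 0.5, 0.0, 1.0, 0.5, 0.0)
    rest = [m.values for m in models[1:]]
    assert rest == sorted(rest)
    again = enumerate_models()
    assert [m.values for m in again] == [m.values for m in models]


def test_category_golden_counts(models):
    """Category split over the 153 models, frozen from the correlation rule."""
    from collections import Counter
    counts = Counter(m.category for m in models)
    assert counts["ranked_value"] == 1
    assert counts["untuned"] == 1
    # frozen by brute-force evaluation of the r > 0.5 rule
    assert counts["value_like"] == 26
    assert counts["other"] == 125
    brute_value_like = 0
    ranked = np.array([1.0, 0.5, 0.0, 1.0, 0.5, 0.0])
    for m in models:
        v = np.asarray(m.values)
        if m.values == tuple(ranked) or np.ptp(v) == 0:
            continue
        if np.corrcoef(v, ranked)[0, 1] > 0.5:
            brute_value_like += 1
    assert brute_value_like == counts["value_like"]


def test_correlation_examples():
    r, cat = correlate_with_ranked((1.0, 0.5, 0.0, 1.0, 0.5, 0.0))
    assert r == 1.0 and cat == "ranked_value"
    r, cat = correlate_with_ranked((1.0,) * 6)
    assert np.isnan(r) and cat == "untuned"
    # odor-set-B CS50/CS- swapped
    r, cat = correlate_with_ranked((1.0, 0.5, 0.0, 1.0, 0.0, 0.5))
    assert np.isclose(r, 0.75) and cat == "value_like"


def test_models_table_shape(models):
    df = models_table(models)
    assert df.shape == (153, 10)
    assert (df.model_id == np.arange(153)).all()


def test_cue_only_selection():
    labels = [{"cues"}, {"cues", "licks"}, {"licks"}, set()]
    mask = tuning.identify_cue_only_neurons(labels)
    assert mask.tolist() == [True, False, False, False]


def test_tie_break_prefers_fewer_levels_then_lower_id(models):
    scores = np.zeros((153, 1))
    scores[[0, 5, 100]] = 0.5  # exact tie between three models
    best = select_best_model(scores, models)
    n_levels = {m.model_id: len(set(m.values)) for m in models}
    candidates = [0, 5, 100]
    expected = min(candidates, key=lambda i: (n_levels[i], i))
    assert best[0] == expected


@pytest.fixture(scope="module")
def tuned_session():
    cfg = TaskConfig(trials_per_block=12, n_blocks=6, seed=41)
    truth = vc.make_population(n_value=3, n_untuned=3, seed=42)
    sess = vc.simulate_session(cfg, truth)
    prep = vc.prepare_session(sess)
    fitter = ScaledCueFitter(prep.trials, prep.F_restricted)
    return sess, prep, fitter


def test_ranked_model_beats_untuned_on_value_neurons(tuned_session, models):
    sess, prep, fitter = tuned_session
    value_cols = np.array([i for i, l in enumerate(sess.truth.labels())
                           if l == "value"])
    ranked = fitter.score_model(models[0].values, value_cols)
    untuned_model = next(m for m in models if m.category == "untuned")
    flat = fitter.score_model(untuned_model.values, value_cols)
    assert (ranked > flat).all()


def test_untuned_neurons_select_untuned_model(tuned_session, models):
    sess, prep, fitter = tuned_session
    cols = np.array([i for i, l in enumerate(sess.truth.labels())
                     if l == "untuned"])
    scores = fit_all_models(fitter, models, cols)
    best = select_best_model(scores, models)
    untuned_id = next(m.model_id for m in models if m.category == "untuned")
    assert (best == untuned_id).all()


def test_zero_rate_neuron_scores_nonpositive(tuned_session, models):
    _, prep, fitter = tuned_session
    silent = np.zeros((prep.F_restricted.shape[0], 1))
    f2 = ScaledCueFitter(prep.trials, silent)
    s = f2.score_model(models[0].values, np.array([0]))
    assert s[0] <= 1e-12


def test_all_zero_scaling_rejected(tuned_session):
    _, prep, fitter = tuned_session
    with pytest.raises(ValueError):
        fitter.score(np.zeros(len(prep.trials)))


def test_shuffled_value_null_confirms_strong_value_neuron(tuned_session, models):
    sess, prep, fitter = tuned_session
    cols = np.array([i for i, l in enumerate(sess.truth.labels())
                     if l == "value"])
    true = fitter.score_model(models[0].values, cols)
    pct = tuning.shuffled_value_null(fitter, true, cols, n=100, seed=1)
    assert (pct > 90).all()
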