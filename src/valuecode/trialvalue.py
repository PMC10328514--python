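"""Trial-value estimation from licking and the neural history model.

The trial-value model predicts the (session-max-normalized) anticipatory
lick count on every trial from cue identity, reward outcomes on the
previous 10 trials of any type, outcomes on the previous 10 trials of the
same cue, and the cue's cumulative presentation count, fit jointly across
sessions by ordinary least squares.  Its per-trial predictions v_t scale
the cue kernel in the neural history model; value/value-like neurons whose
history-model fit beats all 153 static tuning models, and survives a
within-cue value-shuffle null at the 95th percentile, are history neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import CUE_LABELS, EventLog
from .tuning import CueTuningModel, ScaledCueFitter, enumerate_models

HISTORY_DEPTH = 10
HISTORY_NULL_PERCENTILE = 95.0
ANTICIPATORY_WINDOW = (0.0, 2.5)


def anticipatory_lick_counts(trials: pd.DataFrame, events: EventLog,
                             window: tuple[float, float] = ANTICIPATORY_WINDOW
                             ) -> np.ndarray:
    """Licks in [onset, onset + 2.5) s per trial (reward licks excluded)."""
    onsets = trials["cue_onset"].to_numpy()
    lo = np.searchsorted(events.lick_times, onsets + window[0])
    hi = np.searchsorted(events.lick_times, onsets + window[1])
    return (hi - lo).astype(float)


def _history_regressors(trials: pd.DataFrame,
                        depth: int = HISTORY_DEPTH) -> tuple[np.ndarray, np.ndarray]:
    """(overall, same-cue) outcome indicator matrices, zero-padded."""
    rewarded = trials["rewarded"].to_numpy().astype(float)
    cue = trials["cue_index"].to_numpy()
    n = rewarded.size
    overall = np.zeros((n, depth))
    for k in range(1, depth + 1):
        overall[k:, k - 1] = rewarded[:-k]
    same = np.zeros((n, depth))
    for c in np.unique(cue):
        sel = np.flatnonzero(cue == c)
        for k in range(1, depth + 1):
            same[sel[k:], k - 1] = rewarded[sel[:-k]]
    return overall, same


@dataclass
class TrialValueFit:
    """Joint linear model of anticipatory licking."""

    result: sm.regression.linear_model.RegressionResults
    design_columns: list[str]
    per_trial_value: list[np.ndarray]  # v_t per session, model prediction

    @property
    def beta_cue(self) -> pd.Series:
        return self.params.filter(like="cue:")

    @property
    def beta_hist_overall(self) -> pd.Series:
        return self.params.filter(like="hist_any:")

    @property
    def beta_hist_cue(self) -> pd.Series:
        return self.params.filter(like="hist_cue:")

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.design_columns)


def fit_trial_value_model(sessions: list[tuple[pd.DataFrame, EventLog]],
                          depth: int = HISTORY_DEPTH) -> TrialValueFit:
    """OLS over all sessions jointly; v_t = model prediction per trial.

    Lick counts are normalized so each session's maximum equals 1.
    Sessions with zero licks in every anticipatory window are excluded.
    """
    X_parts, y_parts, kept = [], [], []
    for trials, events in sessions:
        y = anticipatory_lick_counts(trials, events)
        if y.max() == 0:
            import warnings
            warnings.warn("session with no anticipatory licks excluded",
                          stacklevel=2)
            continue
        y = y / y.max()
        cue = trials["cue_index"].to_numpy()
        cue_dummies = np.zeros((cue.size, 6))
        cue_dummies[np.arange(cue.size), cue] = 1.0
        overall, same = _history_regressors(trials, depth)
        count = np.zeros(cue.size)
        for c in np.unique(cue):
            sel = np.flatnonzero(cue == c)
            count[sel] = np.arange(sel.size)
        X_parts.append(np.hstack([cue_dummies, overall, same, count[:, None]]))
        y_parts.append(y)
        kept.append(trials)
    if not X_parts:
        raise ValueError("no usable sessions")
    cols = ([f"cue:{c}" for c in CUE_LABELS]
            + [f"hist_any:{k}" for k in range(1, depth + 1)]
            + [f"hist_cue:{k}" for k in range(1, depth + 1)]
            + ["cue_count"])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    res = sm.OLS(y, X).fit()
    preds, start = [], 0
    for Xi in X_parts:
        preds.append(res.predict(Xi))
        start += Xi.shape[0]
    return TrialValueFit(result=res, design_columns=cols, per_trial_value=preds)


def fit_history_model(fitter: ScaledCueFitter, v_t: np.ndarray,
                      neuron_cols: np.ndarray) -> np.ndarray:
    """Score of the history model (cue kernel scaled by per-trial value).

    v_t is clipped at 0 (the linear lick model can dip slightly below 0 on
    CS- trials; scaled designs require nonnegative stripes).
    """
    v_t = np.asarray(v_t, dtype=float)
    if v_t.size != len(fitter.trials):
        raise ValueError("need one trial value per trial")
    if np.any(~np.isfinite(v_t)):
        raise ValueError("trial values must be finite")
    return fitter.score(np.clip(v_t, 0.0, None), neuron_cols)


def history_candidates(history_scores: np.ndarray,
                       static_scores: np.ndarray) -> np.ndarray:
    """History-candidate mask: the history model beats all static models."""
    return history_scores > static_scores.max(axis=0)


def history_shuffle_null(fitter: ScaledCueFitter, v_t: np.ndarray,
                         true_scores: np.ndarray, neuron_cols: np.ndarray,
                         n: int = 1000, seed: int = 0) -> np.ndarray:
    """Percentile of the history-model score within a null where v_t is
    permuted within each cue (preserving each cue's value distribution but
    destroying its link to specific trials)."""
    if n < 100:
        import warnings
        warnings.warn("fewer than 100 null iterations", stacklevel=2)
    rng = np.random.default_rng(seed)
    v_t = np.clip(np.asarray(v_t, dtype=float), 0.0, None)
    cue = fitter.cue_index
    null = np.empty((n, neuron_cols.size))
    for i in range(n):
        v_shuf = v_t.copy()
        for c in np.unique(cue):
            sel = np.flatnonzero(cue == c)
            v_shuf[sel] = v_t[sel[rng.permutation(sel.size)]]
        null[i] = fitter.score(v_shuf, neuron_cols)
    return 100.0 * (true_scores[None, :] > null).mean(axis=0)


def flag_history_neurons(fitter: ScaledCueFitter, v_t: np.ndarray,
                         neuron_cols: np.ndarray,
                         static_scores: np.ndarray | None = None,
                         models: list[CueTuningModel] | None = None,
                         n_null: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Full history classification for value/value-like neurons.

    Returns per neuron: history score, best static score, candidate flag,
    null percentile (nan for non-candidates), and the final history flag.
    """
    from .tuning import fit_all_models
    models = models or enumerate_models()
    if static_scores is None:
        static_scores = fit_all_models(fitter, models, neuron_cols)
    hist = fit_history_model(fitter, v_t, neuron_cols)
    cand = history_candidates(hist, static_scores)
    pct = np.full(neuron_cols.size, np.nan)
    if cand.any():
        idx = np.flatnonzero(cand)
        pct[idx] = history_shuffle_null(fitter, v_t, hist[idx],
                                        neuron_cols[idx], n=n_null, seed=seed)
    return pd.DataFrame({
        "neuron_id": neuron_cols,
        "history_score": hist,
        "best_static_score": static_scores.max(axis=0),
        "candidate": cand,
        "null_percentile": pct,
        "history": cand & (pct > HISTORY_NULL_PERCENTILE),
    })


def compare_history_vs_licks(restricted_design, F: np.ndarray,
                             trials: pd.DataFrame, fitter: ScaledCueFitter,
                             v_t: np.ndarray, neuron_cols: np.ndarray,
                             lambdas=None) -> pd.DataFrame:
    """Held-out variance explained of a licks-only model versus the history
    model, per neuron."""
    from .enet import LAMBDA_GRID, cv_elastic_net
    lambdas = lambdas or LAMBDA_GRID
    lick_design = restricted_design.drop_groups(["cues"])
    fit = cv_elastic_net(lick_design.X, F[:, neuron_cols], fitter.fold_rows,
                         lambdas=lambdas, store_cv_pred=False, final_fit=False)
    hist = fit_history_model(fitter, v_t, neuron_cols)
    return pd.DataFrame({"neuron_id": neuron_cols,
                         "lick_score": fit.cv_r2,
                         "history_score": hist})
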