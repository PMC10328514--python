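"""Cross-session coding stability for tracked neurons.

Consumes populations whose neuron identities are already matched across
sessions (the generator provides this directly; real data would supply a
matching table).  Three analyses: (1) percentile of each neuron's
own-activity correlation on the next day among correlations with all other
neurons, (2) transfer of GLM kernels fit on one session to predict other
sessions (normalized to cross-validated training performance, against a
trial-shuffle control), (3) unique predictor variance per cell category
refit independently per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .glm import SessionFit, fit_session, unique_variance
from .psth import PsthTensor


@dataclass
class TrackedSession:
    """One session of a tracked population (consistent neuron order)."""

    trials: pd.DataFrame
    F: np.ndarray                 # z-scored activity at design bins
    design: DesignMatrix
    psth: PsthTensor              # z-scored, all trials


def activity_profiles(psth: PsthTensor) -> np.ndarray:
    """Concatenated per-cue trial-averaged PSTHs, one row per neuron."""
    v = psth.values
    return v.reshape(v.shape[0], -1)


def crossday_correlation_percentile(profiles_a: np.ndarray,
                                    profiles_b: np.ndarray,
                                    n_shuffles: int = 100,
                                    seed: int = 0) -> dict:
    """Self-match percentile per neuron between consecutive sessions.

    Correlates neuron i's day-a profile with every neuron's day-b profile;
    the percentile of the self correlation among all of them quantifies
    identity stability.  The shuffle control permutes neuron identity on
    day b.  Returns percentiles, their shuffle counterpart, and a Wilcoxon
    signed-rank test of self vs shuffled percentiles across neurons.
    """
    n = profiles_a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 tracked neurons")
    a = profiles_a - profiles_a.mean(axis=1, keepdims=True)
    b = profiles_b - profiles_b.mean(axis=1, keepdims=True)
    a /= np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-12)
    b /= np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
    corr = a @ b.T  # corr[i, j] = r(day-a neuron i, day-b neuron j)

    def pct(match: np.ndarray) -> np.ndarray:
        # percentile of the matched correlation among correlations of the
        # same day-a neuron with all OTHER day-b neurons
        out = np.empty(n)
        for i in range(n):
            ref = np.delete(corr[i], match[i])
            out[i] = 100.0 * np.mean(ref < corr[i, match[i]])
        return out

    self_pct = pct(np.arange(n))
    rng = np.random.default_rng(seed)
    shuf = np.empty((n_shuffles, n))
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        shuf[s] = pct(perm)
    shuffle_pct = shuf.mean(axis=0)
    diff = self_pct - shuffle_pct
    if np.allclose(diff, 0):
        w = {"statistic": np.nan, "pvalue": 1.0}
    else:
        res = stats.wilcoxon(self_pct, shuffle_pct)
        w = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
    return {"percentile": self_pct, "shuffle_percentile": shuffle_pct,
            "median": float(np.median(self_pct)), "wilcoxon": w}


def _corr_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = (A * B).sum(axis=0)
    den = np.sqrt((A**2).sum(axis=0) * (B**2).sum(axis=0))
    return num / np.maximum(den, 1e-12)


def _third_rows(design: DesignMatrix, third: int) -> np.ndarray:
    n_trials = design.segments.n_trials
    w = design.segments.n_bins_per_trial
    edges = np.linspace(0, n_trials, 4).astype(int)
    t0, t1 = edges[third], edges[third + 1]
    return np.arange(t0 * w, t1 * w)


def model_transfer(train: TrackedSession, tests: list[TrackedSession],
                   train_fit: SessionFit | None = None,
                   n_shuffles: int = 20, seed: int = 0) -> pd.DataFrame:
    """Predict held sessions from training-session kernels.

    Each test session's activity is predicted from its own event times
    through the trained kernels; per-neuron Pearson correlation of
    prediction and truth, per session third, normalized by the training
    session's cross-validated correlation.  The trial-shuffle control
    correlates predictions with trial-permuted activity (within the same
    third), which preserves within-trial temporal structure.
    """
    if train_fit is None:
        train_fit = fit_session(train.design, train.F, train.trials,
                                store_cv_pred=True)
    K = train_fit.kernels()
    intercept = train_fit.enet.intercept
    norm = _corr_cols(train_fit.enet.cv_pred, train.F)
    norm = np.where(np.abs(norm) < 0.05, np.nan, norm)  # unfit neurons
    rng = np.random.default_rng(seed)
    rows = []
    for si, sess in enumerate(tests):
        pred = np.asarray(sess.design.X @ K) + intercept
        for third in range(3):
            rsel = _third_rows(sess.design, third)
            r_true = _corr_cols(pred[rsel], sess.F[rsel])
            w = sess.design.segments.n_bins_per_trial
            trials_in = rsel.size // w
            shuf_acc = np.zeros(sess.F.shape[1])
            for _ in range(n_shuffles):
                perm = rng.permutation(trials_in)
                rows_perm = (rsel.reshape(trials_in, w)[perm]).ravel()
                shuf_acc += _corr_cols(pred[rsel], sess.F[rows_perm])
            rows.append({
                "session": si, "third": third,
                "corr": float(np.nanmean(r_true / norm)),
                "shuffle_corr": float(np.nanmean(shuf_acc / n_shuffles / norm)),
            })
    return pd.DataFrame(rows)


def category_variance_across_days(sessions: list[TrackedSession],
                                  reference_labels: list[set[str]],
                                  groups=("cues", "licks", "reward"),
                                  r: int = 20) -> pd.DataFrame:
    """Mean unique variance per reference-session category per day."""
    def cat_of(ls: set[str]) -> str:
        if "cues" in ls and "licks" in ls:
            return "both"
        if "cues" in ls:
            return "cue"
        if "licks" in ls:
            return "lick"
        return "neither"
    cats = np.array([cat_of(ls) for ls in reference_labels])
    rows = []
    for day, sess in enumerate(sessions):
        table, _ = unique_variance(sess.design, sess.F, sess.trials,
                                   groups=groups, r=r)
        for cat in ("cue", "lick", "both", "neither"):
            sel = cats == cat
            if not sel.any():
                continue
            row = {"day": day, "category": cat, "n": int(sel.sum())}
            for g in groups:
                row[f"delta_{g}"] = float(table.delta_r2[g][sel].mean())
            rows.append(row)
    return pd.DataFrame(rows)
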