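"""Cue-identity and cue-value decoding from single neurons and
pseudo-ensembles.

Single neurons: 6-way linear discriminant per 0.25 s bin (-0.5 to 2.5 s),
fivefold cross-validation, 50 trials per cue.  Pseudo-ensembles: activity
pooled 1-2.5 s from cue onset, trials resampled independently per neuron
within cue (sessions are not simultaneous), diagonal-regularized
discriminant (gamma = 1), accuracy distribution over bootstrap neuron
selections.  Value decoding regresses cue value (0 / 0.5 / 1) with an
elastic net (alpha = 0.5) trained on a balanced set that excludes every
trial of the held-out cue, then bands predictions into CS- / CS50 / CS+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .enet import LAMBDA_GRID, cv_elastic_net, kfold_trials
from .psth import BinnedActivity
from .task import CUE_LABELS

SINGLE_BIN = 0.25
SINGLE_WINDOW = (-0.5, 2.5)
POOL_WINDOW = (1.0, 2.5)
TRIALS_PER_CUE = 50
ENSEMBLE_SIZES = (1, 5, 10, 25, 50, 75, 100, 200)
#: Predicted-value bands: CS- [-0.25, 0.25), CS50 [0.25, 0.75),
#: CS+ [0.75, 1.25]; predictions outside are counted incorrect.
VALUE_BANDS = ((-0.25, 0.25), (0.25, 0.75), (0.75, 1.25))
CLASS_VALUES = {"+": 1.0, "50": 0.5, "-": 0.0}


@dataclass
class DecoderConfig:
    bin_width: float = SINGLE_BIN
    window: tuple[float, float] = SINGLE_WINDOW
    pool_window: tuple[float, float] = POOL_WINDOW
    trials_per_cue: int = TRIALS_PER_CUE
    cv_folds: int = 5
    ensemble_sizes: tuple[int, ...] = ENSEMBLE_SIZES
    n_bootstrap: int = 1000
    lda_gamma: float = 1.0


def event_locked_features(activity: BinnedActivity, onsets: np.ndarray,
                          edges: np.ndarray) -> np.ndarray:
    """Mean activity in windows [onset+edges[k], onset+edges[k+1]) per trial.

    Returns (n_trials, n_windows, n_neurons); robust to non-integer ratios
    between the window width and the activity bin width.
    """
    t_bins = activity.times()
    out = np.empty((onsets.size, edges.size - 1, activity.n_neurons))
    for i, t in enumerate(onsets):
        idx = np.searchsorted(t_bins, t + edges, side="left")
        for k in range(edges.size - 1):
            sl = activity.values[idx[k]: idx[k + 1]]
            out[i, k] = sl.mean(axis=0) if sl.size else 0.0
    return out


def select_trials(trials: pd.DataFrame, per_cue: int,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random ``per_cue`` trial indices (positions) for each cue."""
    out = {}
    for c in CUE_LABELS:
        sel = np.flatnonzero((trials["cue_id"] == c).to_numpy())
        if sel.size < per_cue:
            raise ValueError(f"cue {c} has {sel.size} < {per_cue} trials")
        out[c] = rng.choice(sel, per_cue, replace=False)
    return out


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        fold[idx] = np.arange(idx.size) % k
    return fold


class DiagonalLDA:
    """Gaussian discriminant with pooled within-class covariance shrunk
    fully to its diagonal (gamma = 1)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DiagonalLDA":
        self.classes_ = np.unique(y)
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        resid = X - self.means_[np.searchsorted(self.classes_, y)]
        var = resid.var(axis=0)
        self.var_ = np.maximum(var, 1e-12)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = ((X[:, None, :] - self.means_[None]) ** 2 / self.var_).sum(axis=2)
        score = -0.5 * d + np.log(self.priors_)
        return self.classes_[score.argmax(axis=1)]


def _cv_accuracy(X: np.ndarray, y: np.ndarray, k: int,
                 rng: np.random.Generator, model: str = "lda") -> float:
    folds = _stratified_folds(y, k, rng)
    correct = 0
    for f in range(k):
        te = folds == f
        clf = DiagonalLDA() if model == "diag" else LinearDiscriminantAnalysis()
        clf.fit(X[~te], y[~te])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / y.size


def decode_single_neuron(features: np.ndarray, config: DecoderConfig | None = None,
                         seed: int = 0) -> np.ndarray:
    """Accuracy over time bins for one neuron.

    ``features``: (6, trials_per_cue, n_bins) activity of one neuron.
    """
    config = config or DecoderConfig()
    rng = np.random.default_rng(seed)
    n_cues, n_trials, n_bins = features.shape
    y = np.repeat(np.arange(n_cues), n_trials)
    acc = np.empty(n_bins)
    for b in range(n_bins):
        X = features[:, :, b].reshape(-1, 1)
        acc[b] = _cv_accuracy(X, y, config.cv_folds, rng, model="lda")
    return acc


@dataclass
class DecoderResult:
    accuracy: np.ndarray
    bootstrap_distribution: np.ndarray = field(default=None)
    predicted_values: np.ndarray | None = None


def decode_ensemble(pooled: np.ndarray, size: int, n_bootstrap: int = 1000,
                    config: DecoderConfig | None = None, seed: int = 0,
                    replace: bool = False) -> DecoderResult:
    """Pseudo-ensemble 6-way decoding accuracy distribution.

    ``pooled``: (n_neurons, 6, trials_per_cue) pooled 1-2.5 s activity.
    Each bootstrap selects ``size`` neurons and shuffles trial indices
    independently per neuron within cue before fivefold CV with the
    diagonal-regularized discriminant.
    """
    config = config or DecoderConfig()
    rng = np.random.default_rng(seed)
    n_neurons, n_cues, n_trials = pooled.shape
    if size > n_neurons and not replace:
        raise ValueError("ensemble size exceeds pool; set replace=True")
    y = np.repeat(np.arange(n_cues), n_trials)
    accs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sel = rng.choice(n_neurons, size, replace=replace)
        X = np.empty((n_cues * n_trials, size))
        for j, nidx in enumerate(sel):
            for c in range(n_cues):
                X[c * n_trials:(c + 1) * n_trials, j] = \
                    pooled[nidx, c, rng.permutation(n_trials)]
        accs[b] = _cv_accuracy(X, y, config.cv_folds, rng, model="diag")
    return DecoderResult(accuracy=accs.mean(), bootstrap_distribution=accs)


def band_of(pred: np.ndarray) -> np.ndarray:
    """Band label per prediction: 0, 0.5, 1, or nan outside all bands.

    Ties at interior edges go to the lower band; the bottom edge -0.25 and
    the top edge 1.25 are included.
    """
    out = np.full(pred.shape, np.nan)
    out[(pred >= VALUE_BANDS[0][0]) & (pred <= VALUE_BANDS[0][1])] = 0.0
    out[(pred > VALUE_BANDS[1][0]) & (pred <= VALUE_BANDS[1][1])] = 0.5
    out[(pred > VALUE_BANDS[2][0]) & (pred <= VALUE_BANDS[2][1])] = 1.0
    return out


def heldout_cue_split(target_cue: str, per_cue: int = TRIALS_PER_CUE
                      ) -> dict[str, int]:
    """Training composition: no trials of the held-out cue, all ``per_cue``
    trials of the same-value cue from the other odor set, and half of each
    for the remaining two value classes in both sets."""
    t_set, t_type = target_cue[0], target_cue[1:]
    other_set = "B" if t_set == "A" else "A"
    comp = {}
    for c in CUE_LABELS:
        s, typ = c[0], c[1:]
        if c == target_cue:
            comp[c] = 0
        elif typ == t_type:
            comp[c] = per_cue if s == other_set else 0
        else:
            comp[c] = per_cue // 2
    return comp


def decode_value_heldout_cue(pooled: np.ndarray, target_cue: str,
                             config: DecoderConfig | None = None,
                             seed: int = 0,
                             lambdas=(0.0,) + LAMBDA_GRID) -> DecoderResult:
    """Train a linear value decoder with the held-out cue fully excluded,
    test on that cue's trials.

    ``pooled``: (n_neurons, 6, trials_per_cue) in canonical cue order.
    Lambda (elastic net, alpha = 0.5) is selected by fivefold CV on the
    training set from the printed grid extended with 0 (the OLS limit).
    Returns per-trial predicted values and banded accuracy.
    """
    config = config or DecoderConfig()
    rng = np.random.default_rng(seed)
    n_neurons, n_cues, per_cue = pooled.shape
    if n_cues != 6:
        raise ValueError("held-out-cue decoding requires both odor sets")
    comp = heldout_cue_split(target_cue, per_cue)
    rows, vals = [], []
    for ci, c in enumerate(CUE_LABELS):
        k = comp[c]
        if k == 0:
            continue
        tsel = rng.choice(per_cue, k, replace=False)
        for t in tsel:
            rows.append(pooled[:, ci, t])
            vals.append(CLASS_VALUES[c[1:]])
    X = np.vstack(rows)
    y = np.asarray(vals)
    folds_t = kfold_trials(y.size, config.cv_folds, seed,
                           strata=(y * 2).astype(int))
    fit = cv_elastic_net(X, y, folds_t, lambdas=lambdas,
                         store_cv_pred=False)
    ci = CUE_LABELS.index(target_cue)
    pred = pooled[:, ci, :].T @ fit.weights[:, 0] + fit.intercept[0]
    true_value = CLASS_VALUES[target_cue[1:]]
    acc = float(np.mean(band_of(pred) == true_value))
    return DecoderResult(accuracy=acc, predicted_values=pred)


def bootstrap_exceedance(dist_a: np.ndarray, dist_b: np.ndarray,
                         n_comparisons: int = 1, alpha: float = 0.05
                         ) -> dict[str, float | bool]:
    """One-way exceedance p-values from paired bootstrap distributions.

    p_a_ge_b is the fraction of iterations where a >= b (ties count toward
    both directions).  Significance flags use a Bonferroni-corrected alpha.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or a.size != b.size:
        raise ValueError("need equal-length nonempty bootstrap arrays")
    p_ab = float(np.mean(a >= b))
    p_ba = float(np.mean(b >= a))
    thr = alpha / n_comparisons
    return {"p_a_ge_b": p_ab, "p_b_ge_a": p_ba,
            "a_less_significant": p_ab < thr, "b_less_significant": p_ba < thr}
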