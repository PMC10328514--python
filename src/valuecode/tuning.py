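"""The 153-model cue-tuning comparison.

Candidate tuning models assign a value in {0, 0.5, 1} to each of the six
cues: every distinct permutation of the multiset {1, 1, 0.5, 0.5, 0, 0}
(90 graded models, including the ranked value model (1, 0.5, 0, 1, 0.5, 0))
plus every binary pattern with k of 6 cues set to 1 (63 models, including
the all-ones "untuned" model).  Each model is fit to a cue neuron as a
single cue kernel scaled by the model's value for the trial's cue (plus
block constants, full rank) and scored by cross-validated variance
explained; the best model classifies the neuron as value / value-like /
untuned / other, with a shuffled-value permutation null confirming value
neurons at the 98th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .design import (CUE_KERNEL_RESTRICTED, RESTRICTED_WINDOW,
                     scaled_cue_design)
from .enet import LAMBDA_GRID, cv_elastic_net, kfold_trials, trial_rows

RANKED_VALUES = (1.0, 0.5, 0.0, 1.0, 0.5, 0.0)
VALUE_LIKE_MIN_CORR = 0.5
NULL_PERCENTILE = 98.0


@dataclass(frozen=True)
class CueTuningModel:
    model_id: int
    values: tuple[float, ...]
    family: str            # graded_permutation | binary_selective
    value_corr: float      # nan for the constant (untuned) vector
    category: str          # ranked_value | value_like | untuned | other


def correlate_with_ranked(values) -> tuple[float, str]:
    """Pearson r with the ranked model, and the category it implies."""
    v = np.asarray(values, dtype=float)
    ranked = np.asarray(RANKED_VALUES)
    if tuple(v) == tuple(ranked):
        return 1.0, "ranked_value"
    if np.ptp(v) == 0:
        # constant vector: correlation undefined; all-ones is "untuned"
        return float("nan"), "untuned"
    r = float(np.corrcoef(v, ranked)[0, 1])
    return r, "value_like" if r > VALUE_LIKE_MIN_CORR else "other"


def enumerate_models() -> list[CueTuningModel]:
    """All 153 distinct tuning models, ranked model first then lexicographic."""
    vectors: set[tuple[float, ...]] = set()
    for perm in permutations((1.0, 1.0, 0.5, 0.5, 0.0, 0.0)):
        vectors.add(perm)
    for k in range(1, 7):
        for ones in combinations(range(6), k):
            v = [0.0] * 6
            for i in ones:
                v[i] = 1.0
            vectors.add(tuple(v))
    ranked = tuple(RANKED_VALUES)
    ordered = [ranked] + sorted(vectors - {ranked})
    models = []
    for i, v in enumerate(ordered):
        fam = ("graded_permutation" if sorted(v) == [0.0, 0.0, 0.5, 0.5, 1.0, 1.0]
               else "binary_selective")
        r, cat = correlate_with_ranked(v)
        models.append(CueTuningModel(model_id=i, values=v, family=fam,
                                     value_corr=r, category=cat))
    return models


def models_table(models: list[CueTuningModel] | None = None) -> pd.DataFrame:
    models = models or enumerate_models()
    return pd.DataFrame({
        "model_id": [m.model_id for m in models],
        **{f"v{i}": [m.values[i] for m in models] for i in range(6)},
        "family": [m.family for m in models],
        "value_corr": [m.value_corr for m in models],
        "category": [m.category for m in models],
    })


def identify_cue_only_neurons(labels: list[set[str]]) -> np.ndarray:
    """Neurons labeled {cue} but not {lick} under the restricted model."""
    return np.array([("cues" in ls) and ("licks" not in ls) for ls in labels])


class ScaledCueFitter:
    """Batched cross-validated fits of value-scaled cue-kernel designs.

    Precomputes the stripe layout, fold splits, and the activity matrix so
    that scoring a new value-per-trial vector only rebuilds a dense T x L
    matrix and runs the Gram-based coordinate descent.
    """

    def __init__(self, trials: pd.DataFrame, F: np.ndarray,
                 cue_kernel: tuple[float, float] = CUE_KERNEL_RESTRICTED,
                 window: tuple[float, float] = RESTRICTED_WINDOW,
                 k_folds: int = 4, fold_seed: int = 0, lambdas=LAMBDA_GRID,
                 block_column: str = "block_index"):
        self.trials = trials
        self.F = np.atleast_2d(F.T).T
        self.window = window
        self.cue_kernel = cue_kernel
        self.lambdas = lambdas
        template = scaled_cue_design(trials, np.ones(len(trials)),
                                     cue_kernel, window, block_column)
        self.template = template
        self.n_lags = template.column_groups["cues"].size
        self.bins_per_trial = template.segments.n_bins_per_trial
        # stripe coordinates: rows/cols/trial of every nonzero cue entry
        coo = template.X[:, template.column_groups["cues"]].tocoo()
        self._rows = coo.row
        self._cols = coo.col
        self._trial_of_entry = coo.row // self.bins_per_trial
        self._const = template.X[:, template.column_groups["const"]].toarray()
        self.cue_index = trials["cue_index"].to_numpy()
        folds_t = kfold_trials(len(trials), k_folds, fold_seed, self.cue_index)
        self.fold_rows = [trial_rows(f, self.bins_per_trial) for f in folds_t]

    def design_for(self, v_per_trial: np.ndarray) -> np.ndarray:
        v_per_trial = np.asarray(v_per_trial, dtype=float)
        if np.any(v_per_trial < 0):
            raise ValueError("per-trial values must be nonnegative")
        X = np.zeros((self.template.n_rows, self.n_lags + self._const.shape[1]))
        X[self._rows, self._cols] = v_per_trial[self._trial_of_entry]
        X[:, self.n_lags:] = self._const
        return X

    def score(self, v_per_trial: np.ndarray,
              neuron_cols: np.ndarray | None = None) -> np.ndarray:
        """Cross-validated variance explained per neuron for one scaling."""
        v_per_trial = np.asarray(v_per_trial, dtype=float)
        if not np.any(v_per_trial):
            raise ValueError("all-zero scaling on every presented trial is "
                             "unidentifiable")
        X = self.design_for(v_per_trial)
        Y = self.F if neuron_cols is None else self.F[:, neuron_cols]
        fit = cv_elastic_net(X, Y, self.fold_rows, lambdas=self.lambdas,
                             store_cv_pred=False, final_fit=False)
        return fit.cv_r2

    def score_model(self, values: tuple[float, ...],
                    neuron_cols: np.ndarray | None = None) -> np.ndarray:
        v = np.asarray(values, dtype=float)[self.cue_index]
        return self.score(v, neuron_cols)


def fit_all_models(fitter: ScaledCueFitter,
                   models: list[CueTuningModel] | None = None,
                   neuron_cols: np.ndarray | None = None) -> np.ndarray:
    """Score matrix (n_models x n_neurons) of every tuning model."""
    models = models or enumerate_models()
    return np.vstack([fitter.score_model(m.values, neuron_cols)
                      for m in models])


def select_best_model(scores: np.ndarray,
                      models: list[CueTuningModel]) -> np.ndarray:
    """Best model id per neuron; ties broken toward fewer distinct value
    levels, then lower model id."""
    n_levels = np.array([len(set(m.values)) for m in models])
    ids = np.array([m.model_id for m in models])
    # lexicographic argmax: score desc, n_levels asc, id asc
    order = np.lexsort((ids, n_levels))
    best = []
    for j in range(scores.shape[1]):
        s = scores[order, j]
        best.append(ids[order[int(np.argmax(s))]])
    return np.asarray(best)


def shuffled_value_null(fitter: ScaledCueFitter, true_scores: np.ndarray,
                        neuron_cols: np.ndarray, n: int = 1000,
                        seed: int = 0) -> np.ndarray:
    """Percentile of each neuron's ranked-model score within a null of
    scores under random cue-to-value permutations of {1,1,0.5,0.5,0,0}.

    One permutation draw per iteration is shared across the batched
    neurons; a draw equal to the identity contributes the true score.
    Returns percentiles (0-100); strict exceedance convention.
    """
    if n < 100:
        import warnings
        warnings.warn("fewer than 100 null iterations", stacklevel=2)
    rng = np.random.default_rng(seed)
    base = np.asarray(RANKED_VALUES)
    null = np.empty((n, neuron_cols.size))
    for i in range(n):
        vals = base[rng.permutation(6)]
        null[i] = fitter.score(vals[fitter.cue_index], neuron_cols)
    return 100.0 * (true_scores[None, :] > null).mean(axis=0)


@dataclass
class BestModelAssignment:
    neuron_id: int
    model_id: int
    fit_score: float
    null_percentile: float
    final_label: str


def classify_cue_neurons(fitter: ScaledCueFitter, neuron_cols: np.ndarray,
                         models: list[CueTuningModel] | None = None,
                         n_null: int = 1000, seed: int = 0,
                         scores: np.ndarray | None = None
                         ) -> list[BestModelAssignment]:
    """Full tuning-model classification for a set of cue-only neurons.

    Best-model selection over the 153 models, then the shuffled-value null
    for neurons whose best model is the ranked value model; final labels
    are value / value_like / untuned / other.
    """
    models = models or enumerate_models()
    if scores is None:
        scores = fit_all_models(fitter, models, neuron_cols)
    best = select_best_model(scores, models)
    by_id = {m.model_id: m for m in models}
    ranked_mask = best == 0
    percentiles = np.full(neuron_cols.size, np.nan)
    if ranked_mask.any():
        idx = np.flatnonzero(ranked_mask)
        percentiles[idx] = shuffled_value_null(
            fitter, scores[0, idx], neuron_cols[idx], n=n_null, seed=seed)
    out = []
    for j, nc in enumerate(neuron_cols):
        m = by_id[int(best[j])]
        if m.category == "ranked_value":
            label = "value" if percentiles[j] > NULL_PERCENTILE else "other"
        else:
            label = m.category
        row = next(i for i, mm in enumerate(models) if mm.model_id == m.model_id)
        out.append(BestModelAssignment(
            neuron_id=int(nc), model_id=m.model_id,
            fit_score=float(scores[row, j]),
            null_percentile=float(percentiles[j]), final_label=label))
    return out
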