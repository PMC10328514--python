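"""Reduced-rank kernel regression with unique-variance classification.

The kernel matrix K (L predictors x N neurons) is factorized as K = B W
with B of rank r, minimizing ||F - P B W||^2.  B is obtained by the
Izenman construction: ridge-stabilized least squares K0, then the SVD of
the fitted values P K0; B = K0 V[:, :r].  Per-neuron weights w_n on the
projected predictors PB are then fit with elastic-net regularization
(alpha = 0.5, the fixed 8-value lambda grid) under trial-level fourfold
cross-validation.

A neuron is deemed to code a predictor group (cues, licks, or reward) when
removing that group's columns and refitting costs more than 2% of
cross-validated variance explained, and the full model itself explains
more than 2%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .design import DesignMatrix
from .enet import (LAMBDA_GRID, ENetFit, cv_elastic_net, kfold_trials,
                   trial_rows)

DEFAULT_RANK = 20
CODING_THRESHOLD = 0.02


@dataclass
class RankBasis:
    """Rank-r temporal basis B (L x r) and projected predictors PB (T x r)."""

    B: np.ndarray
    PB: np.ndarray
    singular_values: np.ndarray

    @property
    def rank(self) -> int:
        return self.B.shape[1]


def fit_rank_basis(design: DesignMatrix, F: np.ndarray, r: int = DEFAULT_RANK,
                   ridge: float = 1e-8) -> RankBasis:
    """Reduced-rank basis from ridge-stabilized OLS + SVD of fitted values."""
    F = np.atleast_2d(F.T).T
    if not np.any(F):
        raise ValueError("all-zero activity matrix")
    X = design.X
    G = (X.T @ X).toarray() if sparse.issparse(X) else X.T @ X
    scale = np.trace(G) / max(G.shape[0], 1)
    G = G + ridge * max(scale, 1.0) * np.eye(G.shape[0])
    K0 = np.linalg.solve(G, np.asarray(X.T @ F))
    fitted = np.asarray(X @ K0)
    r = min(r, min(fitted.shape), K0.shape[1])
    _, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    B = K0 @ Vt.T[:, :r]
    PB = np.asarray(X @ B)
    return RankBasis(B=B, PB=PB, singular_values=s[:r])


def _basis_from_rows(design: DesignMatrix, F: np.ndarray,
                     rows: np.ndarray, r: int, ridge: float = 1e-8) -> np.ndarray:
    """Basis B estimated from a subset of rows (training folds only)."""
    X = design.X[rows]
    G = (X.T @ X).toarray() if sparse.issparse(X) else X.T @ X
    scale = np.trace(G) / max(G.shape[0], 1)
    G = G + ridge * max(scale, 1.0) * np.eye(G.shape[0])
    K0 = np.linalg.solve(G, np.asarray(X.T @ F[rows]))
    fitted = np.asarray(X @ K0)
    r = min(r, min(fitted.shape), K0.shape[1])
    _, _, Vt = np.linalg.svd(fitted, full_matrices=False)
    return K0 @ Vt.T[:, :r]


def cv_reduced_rank(design: DesignMatrix, F: np.ndarray,
                    fold_row_sets: list[np.ndarray], r: int,
                    lambdas=LAMBDA_GRID, tol: float = 1e-4,
                    store_cv_pred: bool = False
                    ) -> tuple[ENetFit, "RankBasis"]:
    """Cross-validated reduced-rank elastic-net fits with the rank basis
    re-estimated inside each training fold.

    Keeping held-out rows out of the basis estimation matters when the
    population is small: a basis computed from all rows carries each
    neuron's own held-out activity and inflates cv_r2 for pure-noise
    neurons.  The final weights/kernels use a basis from all rows.
    """
    from .enet import Standardizer, _gram, coordinate_descent
    F = np.atleast_2d(F.T).T
    T, m = F.shape
    lambdas = sorted(lambdas, reverse=True)
    n_lam = len(lambdas)
    sse = np.zeros((n_lam, m))
    sstot = np.zeros(m)
    cv_pred = np.full((n_lam, T, m), np.nan) if store_cv_pred else None
    all_rows = np.arange(T)
    for test_rows in fold_row_sets:
        train_rows = np.setdiff1d(all_rows, test_rows)
        B = _basis_from_rows(design, F, train_rows, r)
        PB = np.asarray(design.X @ B)
        std = Standardizer.fit(PB[train_rows])
        Xtr = std.transform(PB[train_rows])
        Xte = std.transform(PB[test_rows])
        G, n = _gram(Xtr)
        ymean = F[train_rows].mean(axis=0)
        C = Xtr.T @ (F[train_rows] - ymean) / n
        W = None
        for li, lam in enumerate(lambdas):
            W = coordinate_descent(G, C, lam, W0=W, tol=tol)
            pred = Xte @ W + ymean
            if store_cv_pred:
                cv_pred[li, test_rows] = pred
            sse[li] += ((F[test_rows] - pred) ** 2).sum(axis=0)
        sstot += ((F[test_rows] - ymean) ** 2).sum(axis=0)
    best = sse.argmin(axis=0)
    cv_r2 = 1.0 - sse[best, np.arange(m)] / np.maximum(sstot, 1e-300)
    cv_r2[sstot < 1e-12] = 0.0
    lambda_sel = np.asarray(lambdas)[best]
    pred_out = (cv_pred[best, :, np.arange(m)].T if store_cv_pred
                else np.empty((0, m)))

    # final fit on all rows (basis from all rows) at the selected penalty
    basis_all = fit_rank_basis(design, F, r)
    std = Standardizer.fit(basis_all.PB)
    Xs = std.transform(basis_all.PB)
    G, n = _gram(Xs)
    ymean = F.mean(axis=0)
    C = Xs.T @ (F - ymean) / n
    W_full = np.zeros((Xs.shape[1], m))
    for li in np.unique(best):
        cols = np.flatnonzero(best == li)
        W_full[:, cols] = coordinate_descent(G, C[:, cols], lambdas[li], tol=tol)
    fitted = Xs @ W_full + ymean
    res = ((F - fitted) ** 2).sum(axis=0)
    tot = np.maximum(((F - ymean) ** 2).sum(axis=0), 1e-300)
    weights = W_full / std.scale[:, None]
    intercept = ymean - std.mean @ weights
    enet = ENetFit(weights=weights, intercept=intercept, lambda_=lambda_sel,
                   cv_r2=cv_r2, train_r2=1.0 - res / tot, cv_pred=pred_out)
    return enet, basis_all


@dataclass
class SessionFit:
    """Full reduced-rank fit of one session."""

    basis: RankBasis
    enet: ENetFit
    design: DesignMatrix
    folds: list[np.ndarray]          # held-out row sets

    @property
    def cv_r2(self) -> np.ndarray:
        return self.enet.cv_r2

    def kernels(self) -> np.ndarray:
        """L x N kernel matrix K = B W (weights mapped back through B)."""
        # enet weights live on PB columns (standardization already undone)
        return self.basis.B @ self.enet.weights

    def kernel_for(self, group: str, neuron: int) -> np.ndarray:
        cols = self.design.column_groups[group]
        return self.kernels()[cols, neuron]


def make_folds(design: DesignMatrix, trials: pd.DataFrame, k: int = 4,
               seed: int = 0) -> list[np.ndarray]:
    """Trial-level folds stratified by cue identity, as row sets."""
    strata = trials["cue_index"].to_numpy()
    tf = kfold_trials(len(trials), k, seed, strata)
    w = design.segments.n_bins_per_trial
    return [trial_rows(f, w) for f in tf]


def fit_session(design: DesignMatrix, F: np.ndarray, trials: pd.DataFrame,
                r: int = DEFAULT_RANK, lambdas=LAMBDA_GRID, k_folds: int = 4,
                fold_seed: int = 0, store_cv_pred: bool = False) -> SessionFit:
    """Rank basis plus per-neuron cross-validated elastic-net fits."""
    counts = trials.groupby("cue_index").size()
    if (counts < k_folds).any():
        raise ValueError("need at least k_folds trials per cue")
    folds = make_folds(design, trials, k_folds, fold_seed)
    enet, basis = cv_reduced_rank(design, F, folds, r, lambdas=lambdas,
                                  store_cv_pred=store_cv_pred)
    # map weights back from PB columns to kernel space lazily (see kernels())
    return SessionFit(basis=basis, enet=enet, design=design, folds=folds)


@dataclass
class UniqueVarianceTable:
    """Per neuron x group drop in cross-validated variance explained."""

    full_cv_r2: np.ndarray
    delta_r2: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        d = {"full_cv_r2": self.full_cv_r2}
        d.update({f"delta_{g}": v for g, v in self.delta_r2.items()})
        return pd.DataFrame(d)


def unique_variance(design: DesignMatrix, F: np.ndarray, trials: pd.DataFrame,
                    groups: tuple[str, ...] = ("cues", "licks", "reward"),
                    r: int = DEFAULT_RANK, lambdas=LAMBDA_GRID,
                    k_folds: int = 4, fold_seed: int = 0,
                    full_fit: SessionFit | None = None,
                    reuse_basis: bool = False) -> tuple[UniqueVarianceTable, SessionFit]:
    """Unique contribution of each predictor group.

    The reduced model drops the group's columns; by default the rank basis
    is recomputed on the reduced design (set ``reuse_basis`` to project the
    full-model basis instead).
    """
    if full_fit is None:
        full_fit = fit_session(design, F, trials, r, lambdas, k_folds, fold_seed)
    deltas: dict[str, np.ndarray] = {}
    for g in groups:
        if g not in design.column_groups:
            raise KeyError(f"unknown predictor group {g!r}")
        red_design = design.drop_groups([g])
        if reuse_basis:
            keep = np.ones(design.n_cols, dtype=bool)
            keep[design.column_groups[g]] = False
            B = full_fit.basis.B[keep]
            PB = np.asarray(red_design.X @ B)
            enet = cv_elastic_net(PB, F, full_fit.folds, lambdas=lambdas,
                                  store_cv_pred=False, final_fit=False)
        else:
            enet, _ = cv_reduced_rank(red_design, F, full_fit.folds, r,
                                      lambdas=lambdas)
        deltas[g] = full_fit.cv_r2 - enet.cv_r2
    return UniqueVarianceTable(full_cv_r2=full_fit.cv_r2, delta_r2=deltas), full_fit


def classify_coding(table: UniqueVarianceTable,
                    threshold: float = CODING_THRESHOLD) -> list[set[str]]:
    """Label sets per neuron: group in labels iff delta_r2 > threshold and
    the full model explains > threshold."""
    n = table.full_cv_r2.size
    out: list[set[str]] = []
    for i in range(n):
        labels = {g for g, d in table.delta_r2.items()
                  if d[i] > threshold and table.full_cv_r2[i] > threshold}
        out.append(labels)
    return out


def shuffle_trial_activity(F: np.ndarray, design: DesignMatrix,
                           perm: np.ndarray,
                           shifts: np.ndarray | None = None) -> np.ndarray:
    """Misalign activity from trial events: reassign each trial's activity
    segment to another trial's rows and circularly shift it within the
    segment.

    The permutation alone breaks lick/reward alignment and the cue-identity
    mapping but leaves the stereotyped cue-locked latency intact (every
    segment has a cue onset at the same within-segment bin), so the
    within-segment shift is what actually decouples activity from the cue
    kernels.  Per-neuron total activity over the design rows is preserved.
    """
    w = design.segments.n_bins_per_trial
    n_trials = design.segments.n_trials
    if shifts is None:
        shifts = np.zeros(n_trials, dtype=int)
    out = np.empty_like(F)
    for t in range(n_trials):
        seg = F[perm[t] * w: (perm[t] + 1) * w]
        out[t * w:(t + 1) * w] = np.roll(seg, int(shifts[t]), axis=0)
    return out


def shuffle_onset_calibration(design: DesignMatrix, F: np.ndarray,
                              trials: pd.DataFrame, n_shuffles: int = 10,
                              threshold: float = CODING_THRESHOLD,
                              groups: tuple[str, ...] = ("cues", "licks", "reward"),
                              r: int = DEFAULT_RANK, seed: int = 0,
                              k_folds: int = 4) -> pd.DataFrame:
    """False-positive labeling rate under trial-onset shuffling.

    Trial onsets are permuted (equivalently, each trial's activity segment
    is assigned to a random other trial) and the full unique-variance
    pipeline re-run; returns the fraction of neurons labeled per group per
    shuffle.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    rows = []
    n = F.shape[1]
    w = design.segments.n_bins_per_trial
    for s in range(n_shuffles):
        perm = rng.permutation(design.segments.n_trials)
        shifts = rng.integers(0, w, design.segments.n_trials)
        Fs = shuffle_trial_activity(F, design, perm, shifts)
        table, _ = unique_variance(design, Fs, trials, groups=groups, r=r,
                                   k_folds=k_folds, fold_seed=seed + s)
        labels = classify_coding(table, threshold)
        row = {"shuffle": s}
        for g in groups:
            row[g] = sum(g in ls for ls in labels) / n
        row["any"] = sum(bool(ls) for ls in labels) / n
        rows.append(row)
    return pd.DataFrame(rows)
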