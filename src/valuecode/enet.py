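"""Elastic-net regression on precomputed Gram matrices.

Objective (per target column y, n rows):

    (1/2n) ||y - Xw - b||^2  +  lambda * (alpha ||w||_1 + (1-alpha)/2 ||w||_2^2)

which is the standard elastic-net parameterization (identical to
scikit-learn's ElasticNet with l1_ratio = alpha).  Columns are centered and
scaled to unit SD before penalization; the intercept absorbs the centering.

The solver is cyclic coordinate descent on the Gram matrix, vectorized over
many target columns sharing one design.  This is what makes the pipeline's
thousands of small refits (cross-validation grids, 153 tuning models,
permutation nulls) affordable; scikit-learn serves as the independent
numerical oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import sparse

#: The elastic-net penalty grid used for every per-neuron fit.
LAMBDA_GRID = (0.001, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5)
ALPHA = 0.5


@njit(cache=True)
def _cd_kernel(G, C, W, denom, thresh, tol, max_iter):  # pragma: no cover
    p, m = C.shape
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gj = G[j]
            for t in range(m):
                rho = C[j, t] + G[j, j] * W[j, t]
                for k in range(p):
                    rho -= gj[k] * W[k, t]
                if denom[j] > 0.0:
                    if rho > thresh:
                        wj = (rho - thresh) / denom[j]
                    elif rho < -thresh:
                        wj = (rho + thresh) / denom[j]
                    else:
                        wj = 0.0
                else:
                    wj = 0.0
                d = abs(wj - W[j, t])
                if d > max_delta:
                    max_delta = d
                W[j, t] = wj
        if max_delta < tol:
            break
    return W


def coordinate_descent(G: np.ndarray, C: np.ndarray, lam: float,
                       alpha: float = ALPHA, W0: np.ndarray | None = None,
                       tol: float = 1e-4, max_iter: int = 1000) -> np.ndarray:
    """Solve the elastic net for all targets at once.

    G = X'X/n (p x p), C = X'Y/n (p x m).  Returns W (p x m).
    """
    p, m = C.shape
    W = np.zeros((p, m)) if W0 is None else W0.copy()
    denom = np.diag(G).copy() + lam * (1.0 - alpha)
    return _cd_kernel(np.ascontiguousarray(G, dtype=np.float64),
                      np.ascontiguousarray(C, dtype=np.float64),
                      np.ascontiguousarray(W, dtype=np.float64),
                      denom.astype(np.float64), float(lam * alpha),
                      float(tol), int(max_iter))


@dataclass
class Standardizer:
    """Column centering/scaling fitted on training rows."""

    mean: np.ndarray
    scale: np.ndarray  # unit for zero-variance columns

    @classmethod
    def fit(cls, X) -> "Standardizer":
        if sparse.issparse(X):
            mean = np.asarray(X.mean(axis=0)).ravel()
            sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        else:
            mean = X.mean(axis=0)
            sq = (X * X).mean(axis=0)
        var = np.maximum(sq - mean**2, 0.0)
        scale = np.sqrt(var)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, X) -> np.ndarray:
        X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        return (X - self.mean) / self.scale


def _gram(Xs: np.ndarray) -> tuple[np.ndarray, float]:
    n = Xs.shape[0]
    return Xs.T @ Xs / n, n


@dataclass
class ENetFit:
    """Cross-validated elastic-net fits for m targets sharing one design."""

    weights: np.ndarray      # p x m, original (unstandardized) scale
    intercept: np.ndarray    # m
    lambda_: np.ndarray      # selected penalty per target
    cv_r2: np.ndarray        # held-out variance explained per target
    train_r2: np.ndarray
    cv_pred: np.ndarray      # T x m held-out predictions (row order of X)

    def predict(self, X) -> np.ndarray:
        X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        return X @ self.weights + self.intercept


def kfold_trials(n_trials: int, k: int, seed: int,
                 strata: np.ndarray | None = None) -> list[np.ndarray]:
    """Trial indices per fold, optionally stratified (e.g. by cue)."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if strata is None:
        strata = np.zeros(n_trials, dtype=int)
    for s in np.unique(strata):
        idx = rng.permutation(np.flatnonzero(strata == s))
        for i, t in enumerate(idx):
            folds[i % k].append(int(t))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def trial_rows(fold_trials_: np.ndarray, bins_per_trial: int) -> np.ndarray:
    return (fold_trials_[:, None] * bins_per_trial
            + np.arange(bins_per_trial)[None, :]).ravel()


def cv_elastic_net(X, Y: np.ndarray, fold_row_sets: list[np.ndarray],
                   lambdas=LAMBDA_GRID, alpha: float = ALPHA,
                   tol: float = 1e-4, store_cv_pred: bool = True,
                   final_fit: bool = True) -> ENetFit:
    """Fit every target with every penalty, select lambda per target by
    held-out squared error (ties -> larger lambda), refit on all rows.

    cv_r2 = 1 - SSE/SStot pooled over held-out bins, with SStot taken
    around each training fold's mean (held-out R^2 may be negative).
    ``store_cv_pred=False`` skips the held-out prediction matrix and
    ``final_fit=False`` skips the full-data refit (score-only callers).
    """
    Y = np.atleast_2d(Y.T).T
    T, m = Y.shape
    lambdas = sorted(lambdas, reverse=True)  # warm start large -> small
    n_lam = len(lambdas)
    sse = np.zeros((n_lam, m))
    sstot = np.zeros(m)
    cv_pred = np.full((n_lam, T, m), np.nan) if store_cv_pred else None
    all_rows = np.arange(T)
    for test_rows in fold_row_sets:
        train_rows = np.setdiff1d(all_rows, test_rows)
        std = Standardizer.fit(X[train_rows])
        Xtr = std.transform(X[train_rows])
        Xte = std.transform(X[test_rows])
        G, n = _gram(Xtr)
        ymean = Y[train_rows].mean(axis=0)
        Yc = Y[train_rows] - ymean
        C = Xtr.T @ Yc / n
        W = None
        for li, lam in enumerate(lambdas):
            W = coordinate_descent(G, C, lam, alpha, W0=W, tol=tol)
            pred = Xte @ W + ymean
            if store_cv_pred:
                cv_pred[li, test_rows] = pred
            sse[li] += ((Y[test_rows] - pred) ** 2).sum(axis=0)
        sstot += ((Y[test_rows] - ymean) ** 2).sum(axis=0)
    best = sse.argmin(axis=0)  # lambdas descending: ties -> larger lambda
    degenerate = sstot < 1e-12
    cv_r2 = 1.0 - sse[best, np.arange(m)] / np.maximum(sstot, 1e-300)
    cv_r2[degenerate] = 0.0  # zero-variance target: no explainable variance
    lambda_sel = np.asarray(lambdas)[best]
    pred_out = (cv_pred[best, :, np.arange(m)].T if store_cv_pred
                else np.empty((0, m)))
    if not final_fit:
        nanv = np.full(m, np.nan)
        return ENetFit(weights=np.empty((0, m)), intercept=nanv,
                       lambda_=lambda_sel, cv_r2=cv_r2, train_r2=nanv,
                       cv_pred=pred_out)

    # final fit on all rows at the selected penalty per target
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    G, n = _gram(Xs)
    ymean = Y.mean(axis=0)
    C = Xs.T @ (Y - ymean) / n
    W_full = np.zeros((Xs.shape[1], m))
    for li in np.unique(best):
        cols = np.flatnonzero(best == li)
        W_full[:, cols] = coordinate_descent(G, C[:, cols], lambdas[li],
                                             alpha, tol=tol)
    fitted = Xs @ W_full + ymean
    res = ((Y - fitted) ** 2).sum(axis=0)
    tot = np.maximum(((Y - ymean) ** 2).sum(axis=0), 1e-300)
    weights = W_full / std.scale[:, None]
    intercept = ymean - std.mean @ weights
    return ENetFit(weights=weights, intercept=intercept, lambda_=lambda_sel,
                   cv_r2=cv_r2, train_r2=1.0 - res / tot, cv_pred=pred_out)
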