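"""Toeplitz predictor matrices for event-kernel regression.

Rows cover a fixed window around each cue onset (full model: -1 to 6.5 s;
restricted model: -1 to 2.5 s) at 0.1 s bins, concatenated across trials;
inter-trial data are discarded and events falling in the gaps are dropped.
Each event contributes a diagonal stripe of ones (or of a per-trial scaling
in value-scaled designs) across its kernel's lag columns, truncated at
trial-segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .psth import session_lick_rate
from .task import CUE_LABELS, EventLog

DESIGN_BIN = 0.1
FULL_WINDOW = (-1.0, 6.5)
RESTRICTED_WINDOW = (-1.0, 2.5)

CUE_KERNEL = (0.0, 5.0)
CUE_KERNEL_RESTRICTED = (0.0, 2.5)
LICK_KERNEL = (-0.3, 0.3)
BOUT_KERNEL = (-0.3, 2.0)
REWARD_KERNEL = (0.0, 4.0)
RATE_SHIFTS = (-0.4, -0.2, 0.0, 0.2, 0.4, 0.6)


@dataclass(frozen=True)
class KernelWindow:
    """Lag support of one predictor kernel, relative to its event."""

    name: str
    t_min: float
    t_max: float
    bin_width: float = DESIGN_BIN

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be < t_max")
        n = (self.t_max - self.t_min) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("kernel window must contain an integral number of lags")

    @property
    def n_lags(self) -> int:
        return int(round((self.t_max - self.t_min) / self.bin_width))

    @property
    def lag0(self) -> int:
        return int(round(self.t_min / self.bin_width))


@dataclass
class Segments:
    """Row layout: one equal-length segment of bins per trial."""

    onsets: np.ndarray          # cue onset per trial (s)
    window: tuple[float, float]
    bin_width: float = DESIGN_BIN

    @property
    def n_bins_per_trial(self) -> int:
        return int(round((self.window[1] - self.window[0]) / self.bin_width))

    @property
    def n_trials(self) -> int:
        return self.onsets.size

    @property
    def n_rows(self) -> int:
        return self.n_trials * self.n_bins_per_trial

    def row_trial(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_trials), self.n_bins_per_trial)

    def trial_rows(self, t: int) -> slice:
        w = self.n_bins_per_trial
        return slice(t * w, (t + 1) * w)

    def row_times(self) -> np.ndarray:
        """Absolute session time of each row's bin start."""
        offs = self.window[0] + np.arange(self.n_bins_per_trial) * self.bin_width
        return (self.onsets[:, None] + offs[None, :]).ravel()

    def locate_events(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map event times to (trial, within-segment bin); drops events
        outside every segment.  Segments must not overlap."""
        times = np.asarray(times, dtype=float)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("event times must be sorted")
        starts = self.onsets + self.window[0]
        idx = np.searchsorted(starts, times, side="right") - 1
        ok = idx >= 0
        rel = np.where(ok, times - starts[np.clip(idx, 0, None)], -1.0)
        span = self.window[1] - self.window[0]
        ok &= (rel >= 0) & (rel < span)
        bins = np.floor(rel[ok] / self.bin_width + 1e-9).astype(int)
        return idx[ok], bins


@dataclass
class DesignMatrix:
    """Sparse T x L predictor matrix with column-group metadata."""

    X: sparse.csr_matrix
    column_names: list[str]
    column_groups: dict[str, np.ndarray]
    segments: Segments

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def drop_groups(self, groups: list[str]) -> "DesignMatrix":
        drop = np.zeros(self.n_cols, dtype=bool)
        for g in groups:
            if g not in self.column_groups:
                raise KeyError(f"unknown predictor group {g!r}")
            drop[self.column_groups[g]] = True
        keep = np.flatnonzero(~drop)
        remap = -np.ones(self.n_cols, dtype=int)
        remap[keep] = np.arange(keep.size)
        new_groups = {g: remap[c] for g, c in self.column_groups.items()
                      if g not in groups}
        return DesignMatrix(X=self.X[:, keep].tocsr(),
                            column_names=[self.column_names[j] for j in keep],
                            column_groups=new_groups, segments=self.segments)


def toeplitz_block(event_times: np.ndarray, window: KernelWindow,
                   segments: Segments,
                   values: np.ndarray | None = None) -> sparse.csr_matrix:
    """Stripe matrix: column j carries lag (lag0 + j) bins from each event.

    ``values``, if given, holds the stripe height per event (value-scaled
    designs); entries are 1 otherwise.  Stripes crossing a segment boundary
    are truncated.
    """
    if window.n_lags * window.bin_width > (segments.window[1] - segments.window[0]):
        raise ValueError("kernel window wider than trial segment")
    trial_idx, bins = segments.locate_events(event_times)
    if values is not None:
        values = np.asarray(values, dtype=float)
        if np.any(values < 0):
            raise ValueError("stripe values must be nonnegative")
        # values indexed per trial of the event
        ev_vals = values[trial_idx]
    else:
        ev_vals = np.ones(trial_idx.size)
    w = segments.n_bins_per_trial
    lags = window.lag0 + np.arange(window.n_lags)
    rows_within = bins[:, None] + lags[None, :]           # events x lags
    cols = np.broadcast_to(np.arange(window.n_lags), rows_within.shape)
    ok = (rows_within >= 0) & (rows_within < w)
    rows = (trial_idx[:, None] * w + rows_within)[ok]
    data = np.broadcast_to(ev_vals[:, None], rows_within.shape)[ok]
    mat = sparse.coo_matrix((data, (rows, cols[ok])),
                            shape=(segments.n_rows, window.n_lags))
    return mat.tocsr()


def _block_constants(trials: pd.DataFrame, segments: Segments,
                     column: str = "block_index") -> tuple[sparse.csr_matrix, list[str]]:
    labels = trials[column].to_numpy()
    uniq = np.unique(labels)
    w = segments.n_bins_per_trial
    rows = np.arange(segments.n_rows)
    col_of_trial = np.searchsorted(uniq, labels)
    cols = np.repeat(col_of_trial, w)
    mat = sparse.coo_matrix((np.ones(rows.size), (rows, cols)),
                            shape=(segments.n_rows, uniq.size)).tocsr()
    return mat, [f"{column}={u}" for u in uniq]


def _rate_columns(events: EventLog, segments: Segments,
                  session_end: float) -> np.ndarray:
    """Session-long smoothed lick rate sampled at design bins, shifted by
    RATE_SHIFTS (column value at row time t is the rate at t - shift)."""
    rate = session_lick_rate(events, session_end + 2.0)
    # mean-resample the source-rate series to the design bin grid
    src = rate.values[:, 0]
    factor = int(round(DESIGN_BIN / rate.bin_width))
    n_out = src.size // factor
    coarse = src[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    row_bins = np.floor(segments.row_times() / DESIGN_BIN + 1e-9).astype(int)
    out = np.zeros((segments.n_rows, len(RATE_SHIFTS)))
    for j, s in enumerate(RATE_SHIFTS):
        idx = row_bins - int(round(s / DESIGN_BIN))
        idx = np.clip(idx, 0, n_out - 1)
        out[:, j] = coarse[idx]
    return out


def _assemble(trials: pd.DataFrame, events: EventLog, segments: Segments,
              cue_kernel: tuple[float, float], include_reward: bool,
              session_end: float, block_column: str = "block_index") -> DesignMatrix:
    blocks: list[sparse.csr_matrix] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {"cues": [], "licks": [], "const": []}
    if include_reward:
        groups["reward"] = []
    onsets = trials["cue_onset"].to_numpy()
    cue_ids = trials["cue_id"].to_numpy()
    col = 0

    def add(mat, base, group):
        nonlocal col
        blocks.append(mat)
        names.extend(f"{base}[{k}]" for k in range(mat.shape[1]))
        groups[group].extend(range(col, col + mat.shape[1]))
        col += mat.shape[1]

    cw = KernelWindow("cue", *cue_kernel)
    present = [c for c in CUE_LABELS if (cue_ids == c).any()]
    for c in present:
        add(toeplitz_block(onsets[cue_ids == c], cw, segments), f"cue:{c}", "cues")
    add(toeplitz_block(events.lick_times, KernelWindow("lick", *LICK_KERNEL),
                       segments), "lick", "licks")
    add(toeplitz_block(events.bout_starts, KernelWindow("bout", *BOUT_KERNEL),
                       segments), "bout", "licks")
    add(sparse.csr_matrix(_rate_columns(events, segments, session_end)),
        "lick_rate", "licks")
    if include_reward:
        add(toeplitz_block(events.reward_consumption_onsets,
                           KernelWindow("reward", *REWARD_KERNEL), segments),
            "reward", "reward")
    cmat, cnames = _block_constants(trials, segments, block_column)
    blocks.append(cmat)
    names.extend(cnames)
    groups["const"].extend(range(col, col + cmat.shape[1]))
    col += cmat.shape[1]
    X = sparse.hstack(blocks, format="csr")
    return DesignMatrix(X=X, column_names=names,
                        column_groups={g: np.asarray(ix, dtype=int)
                                       for g, ix in groups.items()},
                        segments=segments)


def assemble_full_design(trials: pd.DataFrame, events: EventLog,
                         session_end: float | None = None,
                         block_column: str = "block_index") -> DesignMatrix:
    """Full model: 6 cue kernels (0-5 s), lick kernel (-0.3-0.3 s), bout
    kernel (-0.3-2 s), 6 shifted lick-rate columns, reward kernel (0-4 s),
    and block constants; rows -1 to 6.5 s per trial."""
    if block_column not in trials.columns:
        raise ValueError(f"missing {block_column!r} labels")
    if session_end is None:
        session_end = float(trials["cue_onset"].iloc[-1]) + 10.0
    seg = Segments(trials["cue_onset"].to_numpy(), FULL_WINDOW)
    return _assemble(trials, events, seg, CUE_KERNEL, True, session_end,
                     block_column)


def assemble_restricted_design(trials: pd.DataFrame, events: EventLog,
                               session_end: float | None = None,
                               block_column: str = "block_index") -> DesignMatrix:
    """Cues + licks only, rows -1 to 2.5 s per trial (no reward group)."""
    if block_column not in trials.columns:
        raise ValueError(f"missing {block_column!r} labels")
    if session_end is None:
        session_end = float(trials["cue_onset"].iloc[-1]) + 10.0
    seg = Segments(trials["cue_onset"].to_numpy(), RESTRICTED_WINDOW)
    return _assemble(trials, events, seg, CUE_KERNEL_RESTRICTED, False,
                     session_end, block_column)


def scaled_cue_design(trials: pd.DataFrame, values_per_trial: np.ndarray,
                      cue_kernel: tuple[float, float] = CUE_KERNEL_RESTRICTED,
                      window: tuple[float, float] = RESTRICTED_WINDOW,
                      block_column: str = "block_index") -> DesignMatrix:
    """Single cue-kernel block whose stripe heights equal the trial's value,
    plus block constants."""
    values_per_trial = np.asarray(values_per_trial, dtype=float)
    if np.any(values_per_trial < 0):
        raise ValueError("per-trial values must be nonnegative")
    if values_per_trial.size != len(trials):
        raise ValueError("need one value per trial")
    seg = Segments(trials["cue_onset"].to_numpy(), window)
    cue = toeplitz_block(trials["cue_onset"].to_numpy(),
                         KernelWindow("cue", *cue_kernel), seg,
                         values=values_per_trial)
    cmat, cnames = _block_constants(trials, seg, block_column)
    X = sparse.hstack([cue, cmat], format="csr")
    names = [f"cue[{k}]" for k in range(cue.shape[1])] + cnames
    groups = {"cues": np.arange(cue.shape[1]),
              "const": cue.shape[1] + np.arange(cmat.shape[1])}
    return DesignMatrix(X=X, column_names=names, column_groups=groups,
                        segments=seg)
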