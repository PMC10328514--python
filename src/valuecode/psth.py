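"""Binning, causal smoothing, PSTHs, and baseline z-scoring.

Spike trains are binned at 0.02 s and smoothed with a causal half-normal
filter (sigma = 300 ms, 50 taps); lick PSTHs use sigma = 800 ms.  PSTHs are
built in 0.1 s bins around cue onset and z-scored against the pooled 2 s
pre-cue baseline across all trials.  Bin edges are half-open [t, t+dt); the
alignment bin 0 starts exactly at cue onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import CUE_LABELS, EventLog

SPIKE_BIN = 0.02
PSTH_BIN = 0.1
SPIKE_SMOOTH_SIGMA = 0.3
LICK_SMOOTH_SIGMA = 0.8
SPIKE_SMOOTH_TAPS = 50
BASELINE_WINDOW = (-2.0, 0.0)


def half_normal_filter(sigma: float, n_taps: int, dt: float) -> np.ndarray:
    """Causal half-normal weights w(k) ~ exp(-(k*dt)^2 / (2 sigma^2)).

    Supported only on the present and past bins (k = 0 .. n_taps-1),
    normalized to sum to 1 so smoothing conserves count mass.
    """
    k = np.arange(n_taps)
    w = np.exp(-((k * dt) ** 2) / (2.0 * sigma**2))
    return w / w.sum()


@dataclass
class BinnedActivity:
    """Neurons-by-time activity in regression orientation (T bins x N).

    ``values[t, n]`` is neuron n's smoothed rate (events/s) in bin
    [t0 + t*bin_width, t0 + (t+1)*bin_width).
    """

    values: np.ndarray
    bin_width: float
    t0: float = 0.0
    zscored: bool = False
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None
    flagged: np.ndarray | None = None  # zero-baseline-SD neurons

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_bins) * self.bin_width


@dataclass
class PsthTensor:
    """Trial-averaged activity: neurons x cues x time bins."""

    values: np.ndarray
    window: tuple[float, float]
    bin_width: float
    cue_labels: tuple[str, ...]
    trial_sets: str = "all"  # all | even | odd
    zscored: bool = False
    flagged: np.ndarray | None = None

    def bin_times(self) -> np.ndarray:
        return self.window[0] + (np.arange(self.values.shape[2]) + 0.5) * self.bin_width


def bin_and_smooth_spikes(spike_trains: list[np.ndarray], session_end: float,
                          bin_width: float = SPIKE_BIN,
                          sigma: float = SPIKE_SMOOTH_SIGMA,
                          n_taps: int = SPIKE_SMOOTH_TAPS) -> BinnedActivity:
    """Bin spike times (0.02 s) and causally smooth to rate units."""
    n_bins = int(np.ceil(session_end / bin_width))
    w = half_normal_filter(sigma, n_taps, bin_width)
    out = np.empty((n_bins, len(spike_trains)))
    edges = np.arange(n_bins + 1) * bin_width
    for i, st in enumerate(spike_trains):
        st = np.asarray(st, dtype=float)
        if st.size and (np.any(np.diff(st) < 0) or st[0] < 0):
            raise ValueError("spike times must be sorted and nonnegative")
        counts, _ = np.histogram(st, bins=edges)
        out[:, i] = np.convolve(counts / bin_width, w)[:n_bins]
    return BinnedActivity(values=out, bin_width=bin_width)


def bin_traces(traces: np.ndarray, fs: float = 15.0,
               sigma: float = SPIKE_SMOOTH_SIGMA) -> BinnedActivity:
    """Smooth deconvolved traces sampled at ``fs`` with the spike filter
    resampled to the native rate, for downstream 0.1 s binning."""
    dt = 1.0 / fs
    n_taps = max(2, int(round(SPIKE_SMOOTH_TAPS * SPIKE_BIN / dt)))
    w = half_normal_filter(sigma, n_taps, dt)
    sm = np.empty_like(traces, dtype=float)
    for j in range(traces.shape[1]):
        sm[:, j] = np.convolve(traces[:, j], w)[: traces.shape[0]]
    return BinnedActivity(values=sm, bin_width=dt)


def rebin(activity: BinnedActivity, bin_width: float = PSTH_BIN) -> BinnedActivity:
    """Mean-rate resampling to coarser bins (units preserved)."""
    factor = bin_width / activity.bin_width
    if abs(factor - round(factor)) > 1e-9:
        # non-integer ratio (e.g. 15 Hz traces): average by time membership
        t = activity.times()
        n_out = int(np.floor(activity.n_bins * activity.bin_width / bin_width))
        idx = np.floor(t / bin_width).astype(int)
        keep = idx < n_out
        sums = np.zeros((n_out, activity.n_neurons))
        cnts = np.zeros(n_out)
        np.add.at(sums, idx[keep], activity.values[keep])
        np.add.at(cnts, idx[keep], 1.0)
        vals = sums / np.maximum(cnts, 1)[:, None]
    else:
        factor = int(round(factor))
        n_out = activity.n_bins // factor
        vals = activity.values[: n_out * factor].reshape(
            n_out, factor, activity.n_neurons).mean(axis=1)
    return BinnedActivity(values=vals, bin_width=bin_width, t0=activity.t0,
                          zscored=activity.zscored,
                          baseline_mean=activity.baseline_mean,
                          baseline_sd=activity.baseline_sd,
                          flagged=activity.flagged)


def _trial_mask(trials: pd.DataFrame, trial_filter: str) -> np.ndarray:
    idx = trials["trial_index"].to_numpy()
    if trial_filter == "all":
        return np.ones(idx.size, dtype=bool)
    if trial_filter == "even":
        return idx % 2 == 0
    if trial_filter == "odd":
        return idx % 2 == 1
    raise ValueError(f"unknown trial_filter {trial_filter!r}")


def align_trials(activity: BinnedActivity, onsets: np.ndarray,
                 window: tuple[float, float],
                 bin_width: float = PSTH_BIN) -> np.ndarray:
    """Per-trial aligned traces: (n_trials, n_bins, n_neurons).

    Trials whose window extends past the recording are rejected.
    """
    act = rebin(activity, bin_width) if activity.bin_width != bin_width else activity
    n_bins = int(round((window[1] - window[0]) / bin_width))
    out = np.empty((onsets.size, n_bins, act.n_neurons))
    for i, t in enumerate(onsets):
        b0 = int(np.floor((t + window[0] - act.t0) / bin_width + 1e-9))
        if b0 < 0 or b0 + n_bins > act.n_bins:
            raise ValueError(f"trial window at onset {t} extends past recording")
        out[i] = act.values[b0: b0 + n_bins]
    return out


def make_psth(activity: BinnedActivity, trials: pd.DataFrame,
              window: tuple[float, float] = (-1.0, 6.5),
              bin_width: float = PSTH_BIN,
              trial_filter: str = "all") -> PsthTensor:
    """Cue-averaged PSTHs in 0.1 s bins around cue onset."""
    mask = _trial_mask(trials, trial_filter)
    sub = trials[mask]
    aligned = align_trials(activity, sub["cue_onset"].to_numpy(), window, bin_width)
    n_bins = aligned.shape[1]
    cues = [c for c in CUE_LABELS if (trials["cue_id"] == c).any()]
    vals = np.zeros((activity.n_neurons, len(cues), n_bins))
    cue_ids = sub["cue_id"].to_numpy()
    for j, c in enumerate(cues):
        sel = cue_ids == c
        if sel.any():
            vals[:, j, :] = aligned[sel].mean(axis=0).T
    return PsthTensor(values=vals, window=window, bin_width=bin_width,
                      cue_labels=tuple(cues), trial_sets=trial_filter,
                      zscored=activity.zscored, flagged=activity.flagged)


def baseline_stats(activity: BinnedActivity, trials: pd.DataFrame,
                   window: tuple[float, float] = BASELINE_WINDOW,
                   bin_width: float = PSTH_BIN) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD per neuron over pooled pre-cue bins across all trials."""
    aligned = align_trials(activity, trials["cue_onset"].to_numpy(), window,
                           bin_width)
    pooled = aligned.reshape(-1, activity.n_neurons)
    return pooled.mean(axis=0), pooled.std(axis=0)


def zscore_to_baseline(obj: BinnedActivity | PsthTensor,
                       activity: BinnedActivity | None = None,
                       trials: pd.DataFrame | None = None,
                       stats: tuple[np.ndarray, np.ndarray] | None = None):
    """Z-score against the pooled 2 s pre-cue baseline.

    For a :class:`BinnedActivity`, pass ``trials`` (stats are computed from
    the object itself).  For a :class:`PsthTensor`, pass the source
    ``activity`` and ``trials`` (or precomputed ``stats``).  Zero-SD
    neurons are flagged and their z-scores set to 0.
    """
    if isinstance(obj, BinnedActivity):
        if obj.zscored:
            raise ValueError("activity is already z-scored")
        mu, sd = stats if stats is not None else baseline_stats(obj, trials)
    else:
        if obj.zscored:
            raise ValueError("PSTH is already z-scored")
        mu, sd = stats if stats is not None else baseline_stats(activity, trials)
    flagged = sd == 0
    safe_sd = np.where(flagged, 1.0, sd)
    if isinstance(obj, BinnedActivity):
        vals = (obj.values - mu) / safe_sd
        vals[:, flagged] = 0.0
        return replace(obj, values=vals, zscored=True, baseline_mean=mu,
                       baseline_sd=sd, flagged=flagged)
    vals = (obj.values - mu[:, None, None]) / safe_sd[:, None, None]
    vals[flagged] = 0.0
    return replace(obj, values=vals, zscored=True, flagged=flagged)


def lick_psth(events: EventLog, trials: pd.DataFrame,
              window: tuple[float, float] = (-1.0, 6.5),
              bin_width: float = PSTH_BIN,
              sigma: float = LICK_SMOOTH_SIGMA,
              trial_filter: str = "all") -> PsthTensor:
    """Lick-rate PSTH: per-trial 0.1 s lick counts smoothed causally
    (sigma = 800 ms) then averaged within cue."""
    mask = _trial_mask(trials, trial_filter)
    sub = trials[mask]
    n_bins = int(round((window[1] - window[0]) / bin_width))
    n_taps = max(2, int(np.ceil(4 * sigma / bin_width)))
    w = half_normal_filter(sigma, n_taps, bin_width)
    cues = [c for c in CUE_LABELS if (trials["cue_id"] == c).any()]
    vals = np.zeros((1, len(cues), n_bins))
    cue_ids = sub["cue_id"].to_numpy()
    onsets = sub["cue_onset"].to_numpy()
    for j, c in enumerate(cues):
        sel = np.flatnonzero(cue_ids == c)
        if sel.size == 0:
            continue
        acc = np.zeros(n_bins)
        for i in sel:
            edges = onsets[i] + window[0] + np.arange(n_bins + 1) * bin_width
            counts, _ = np.histogram(events.lick_times, bins=edges)
            acc += np.convolve(counts / bin_width, w)[:n_bins]
        vals[0, j, :] = acc / sel.size
    return PsthTensor(values=vals, window=window, bin_width=bin_width,
                      cue_labels=tuple(cues), trial_sets=trial_filter)


def session_lick_rate(events: EventLog, session_end: float,
                      source_bin: float = SPIKE_BIN,
                      sigma: float = LICK_SMOOTH_SIGMA,
                      n_taps: int = 25) -> BinnedActivity:
    """Session-long smoothed lick rate (for the GLM lick-rate regressor):
    counts in source bins smoothed with a 25-tap causal half-normal."""
    n_bins = int(np.ceil(session_end / source_bin))
    edges = np.arange(n_bins + 1) * source_bin
    counts, _ = np.histogram(events.lick_times, bins=edges)
    w = half_normal_filter(sigma, n_taps, source_bin)
    rate = np.convolve(counts / source_bin, w)[:n_bins]
    return BinnedActivity(values=rate[:, None], bin_width=source_bin)


def classify_polarity(psth_even: PsthTensor,
                      response_window: tuple[float, float] = (0.0, 2.5)) -> np.ndarray:
    """Per neuron: "above" or "below" baseline by the sign of the
    peak-magnitude deviation in 0-2.5 s on even trials (tie -> above)."""
    if not psth_even.zscored:
        raise ValueError("polarity requires a z-scored PSTH")
    t = psth_even.bin_times()
    sel = (t >= response_window[0]) & (t < response_window[1])
    seg = psth_even.values[:, :, sel]
    flat = seg.reshape(seg.shape[0], -1)
    peak = flat[np.arange(flat.shape[0]), np.abs(flat).argmax(axis=1)]
    return np.where(peak >= 0, "above", "below")
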