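"""Population coding-dimension projection, trajectory angle, and
trial-value slope.

The coding dimension for a cue pair (e.g. CS+ vs CS-) is the length-N
vector of each neuron's signed peak difference between the two cues'
max-normalized even-trial PSTHs, searched over tiled 0.5 s bins in
0-2.5 s.  Multiplying it against the original z-scored peak-bin states of
the defining cues gives the constants that map projections onto a 0 (CS-)
to 1 (CS+) scale.  Held-out (odd-trial) activity, other-odor-set activity,
or per-trial activity is then projected onto this scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psth import PsthTensor

PEAK_SEARCH_WINDOW = (0.0, 2.5)
PEAK_BIN_WIDTH = 0.5
SLOPE_WINDOW = (1.0, 2.5)
N_BOOTSTRAP = 5000


def max_normalize(psth: PsthTensor) -> np.ndarray:
    """Each neuron's concatenated 6-cue PSTH scaled to peak at -1 or 1."""
    v = psth.values
    peak = np.abs(v.reshape(v.shape[0], -1)).max(axis=1)
    peak[peak == 0] = 1.0
    return v / peak[:, None, None]


@dataclass
class CodingProjection:
    """A 0-to-1 cue coding scale defined from even trials."""

    difference_vector: np.ndarray  # d, length N (signed)
    peak_bins: np.ndarray          # tiled 0.5 s bin index per neuron
    scale_zero: float              # d . (low-cue peak state), maps to 0
    scale_one: float               # d . (high-cue peak state), maps to 1
    window: tuple[float, float]
    bin_width: float

    def project_states(self, Z: np.ndarray) -> np.ndarray:
        """Project neuron-state columns (N x ...) onto the 0-1 scale."""
        num = np.tensordot(self.difference_vector, Z, axes=(0, 0))
        return (num - self.scale_zero) / (self.scale_one - self.scale_zero)


def _tiled_means(values: np.ndarray, bin_times: np.ndarray,
                 window=PEAK_SEARCH_WINDOW, width=PEAK_BIN_WIDTH) -> np.ndarray:
    """Average over non-overlapping 0.5 s bins: (..., n_tiles)."""
    n_tiles = int(round((window[1] - window[0]) / width))
    out = []
    for k in range(n_tiles):
        lo = window[0] + k * width
        sel = (bin_times >= lo) & (bin_times < lo + width)
        out.append(values[..., sel].mean(axis=-1))
    return np.stack(out, axis=-1)


def build_coding_dimension(psth_even: PsthTensor, high_cue: str, low_cue: str,
                           neuron_subset: np.ndarray | None = None) -> CodingProjection:
    """Coding dimension from even-trial PSTHs for a cue pair.

    The difference vector comes from max-normalized PSTHs; the 0/1 scaling
    constants from the original z-scored values at each neuron's peak bin.
    """
    if psth_even.values.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    t = psth_even.bin_times()
    norm = max_normalize(psth_even)
    z = psth_even.values
    if neuron_subset is not None:
        norm = norm[neuron_subset]
        z = z[neuron_subset]
    hi = psth_even.cue_labels.index(high_cue)
    lo = psth_even.cue_labels.index(low_cue)
    tiles_norm = _tiled_means(norm[:, hi] - norm[:, lo], t)
    peak_bins = np.abs(tiles_norm).argmax(axis=1)
    n = np.arange(norm.shape[0])
    d = tiles_norm[n, peak_bins]
    tiles_hi = _tiled_means(z[:, hi], t)
    tiles_lo = _tiled_means(z[:, lo], t)
    scale_one = float(d @ tiles_hi[n, peak_bins])
    scale_zero = float(d @ tiles_lo[n, peak_bins])
    if scale_one == scale_zero:
        raise ValueError("degenerate coding dimension: identical endpoints")
    return CodingProjection(difference_vector=d, peak_bins=peak_bins,
                            scale_zero=scale_zero, scale_one=scale_one,
                            window=psth_even.window,
                            bin_width=psth_even.bin_width)


def project(proj: CodingProjection, psth: PsthTensor, cue: str,
            neuron_subset: np.ndarray | None = None) -> np.ndarray:
    """Scalar trajectory (per 0.1 s bin) of one cue's PSTH on the 0-1 scale."""
    z = psth.values[:, psth.cue_labels.index(cue), :]
    if neuron_subset is not None:
        z = z[neuron_subset]
    if z.shape[0] != proj.difference_vector.size:
        raise ValueError("neuron count mismatch between projection and activity")
    return proj.project_states(z)


def project_trials(proj: CodingProjection, aligned: np.ndarray,
                   bin_times: np.ndarray,
                   window: tuple[float, float] = SLOPE_WINDOW) -> np.ndarray:
    """Per-trial scalar projection of mean activity in ``window``.

    ``aligned``: (n_trials, n_bins, n_neurons) z-scored traces.
    """
    sel = (bin_times >= window[0]) & (bin_times < window[1])
    states = aligned[:, sel, :].mean(axis=1).T  # N x trials
    return proj.project_states(states)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate zero-length trajectory vector")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def trajectory_angle(psth_even: PsthTensor, psth_odd: PsthTensor,
                     plus_cue: str = "A+", fifty_cue: str = "A50",
                     minus_cue: str = "A-", n_bootstrap: int = N_BOOTSTRAP,
                     seed: int = 0) -> np.ndarray:
    """Bootstrap distribution of the angle between CS+ and CS50 baseline-to-
    peak vectors in the (CS-/CS+, CS-/CS50) projection plane.

    Neurons are resampled with replacement; both coding dimensions are
    rebuilt on each resample.  The baseline point is the pre-cue mean; the
    peak point is the trajectory bin (0-2.5 s) farthest from baseline.
    """
    rng = np.random.default_rng(seed)
    t = psth_odd.bin_times()
    base_sel = t < 0
    resp_sel = (t >= PEAK_SEARCH_WINDOW[0]) & (t < PEAK_SEARCH_WINDOW[1])
    n = psth_even.values.shape[0]
    angles = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sub = rng.integers(0, n, n) if n_bootstrap > 1 else np.arange(n)
        try:
            proj_pm = build_coding_dimension(psth_even, plus_cue, minus_cue, sub)
            proj_fm = build_coding_dimension(psth_even, fifty_cue, minus_cue, sub)
            pts = {}
            for cue in (plus_cue, fifty_cue):
                x = project(proj_pm, psth_odd, cue, sub)
                y = project(proj_fm, psth_odd, cue, sub)
                base = np.array([x[base_sel].mean(), y[base_sel].mean()])
                xy = np.stack([x[resp_sel], y[resp_sel]], axis=1)
                dist = np.linalg.norm(xy - base, axis=1)
                pts[cue] = xy[dist.argmax()] - base
            angles[b] = _angle_deg(pts[plus_cue], pts[fifty_cue])
        except ValueError:
            angles[b] = np.nan
    return angles


def value_slope(psth_even: PsthTensor, aligned: np.ndarray,
                bin_times: np.ndarray, trial_values: np.ndarray,
                plus_cue: str = "A+", minus_cue: str = "A-",
                n_bootstrap: int = N_BOOTSTRAP, seed: int = 0) -> dict:
    """Slope of CS50-trial projections (CS-/CS+ dimension, mean 1-2.5 s)
    regressed on trial value, with a neuron-bootstrap distribution.

    ``aligned``: (n_CS50_trials, n_bins, N) z-scored traces;
    ``trial_values``: the lick-model value estimate per those trials.
    """
    if np.unique(trial_values).size < 2:
        raise ValueError("need at least 2 distinct trial values")
    rng = np.random.default_rng(seed)
    n = psth_even.values.shape[0]
    vc = trial_values - trial_values.mean()
    denom = float(vc @ vc)
    slopes = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sub = rng.integers(0, n, n)
        try:
            proj = build_coding_dimension(psth_even, plus_cue, minus_cue, sub)
            p = project_trials(proj, aligned[:, :, sub], bin_times)
            slopes[b] = float(vc @ (p - p.mean())) / denom
        except ValueError:
            slopes[b] = np.nan
    slopes = slopes[np.isfinite(slopes)]
    p_le_zero = float(np.mean(slopes <= 0)) if slopes.size else np.nan
    return {"slope": float(np.mean(slopes)), "sd": float(np.std(slopes)),
            "bootstrap": slopes, "p_le_zero": p_le_zero}
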