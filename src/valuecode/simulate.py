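"""Forward model: spike trains from known kernels, tuning, and gains.

Each neuron's instantaneous rate is

    rate(t) = max(0, baseline
                     + cue_gain * s_t * k_cue(t - cue_onset)
                     + lick_gain * sum_licks k_lick(t - t_lick)
                     + reward_gain * k_reward(t - t_consumption))

where s_t scales the cue response on trial t: the neuron's tuning value for
the trial's cue, shifted toward the generative trial value in proportion to
``history_gain`` (0 = static tuning, 1 = fully trial-value scaled).
Spikes are Poisson counts in 1 ms bins; trace mode adds Gaussian noise to
the rate sampled at 15 Hz instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import EventLog, TaskConfig, generate_task

DT = 0.001  # simulation grid, seconds

RANKED_TUNING = np.array([1.0, 0.5, 0.0, 1.0, 0.5, 0.0])
UNTUNED_TUNING = np.ones(6)


def cue_kernel_shape(duration: float = 2.5, dt: float = DT,
                     peak: float = 0.4) -> np.ndarray:
    """Unit-peak gamma-like bump on [0, duration): rises to 1 at ``peak`` s."""
    t = np.arange(0.0, duration, dt)
    k = (t / peak) * np.exp(1.0 - t / peak)
    return k / k.max()


def mixed_cue_kernel(params: np.ndarray, duration: float = 2.5,
                     dt: float = DT) -> np.ndarray:
    """Per-neuron cue kernel: a weighted mixture of gamma bumps.

    ``params`` rows are (weight, peak_time); the mixture is normalized to
    unit peak.  Real neurons have individually distinctive response shapes
    (latency, duration, multiphasic bumps); a random mixture per neuron
    reproduces that distinctiveness, which the cross-day identity analyses
    rely on.
    """
    k = np.zeros(int(round(duration / dt)))
    for w, pk in params:
        if w > 0:
            k += w * cue_kernel_shape(duration, dt, peak=pk)
    peak = k.max()
    return k / peak if peak > 0 else k


def lick_kernel_shape(duration: float = 0.3, dt: float = DT) -> np.ndarray:
    """Unit-peak bump on [0, duration) peaking at 0.1 s."""
    t = np.arange(0.0, duration, dt)
    k = np.sin(np.clip(t / duration, 0, 1) * np.pi) ** 2
    return k / max(k.max(), 1e-12)


def reward_kernel_shape(duration: float = 2.0, dt: float = DT) -> np.ndarray:
    """Unit-peak rise-and-decay on [0, duration)."""
    t = np.arange(0.0, duration, dt)
    k = (1 - np.exp(-t / 0.15)) * np.exp(-t / 0.8)
    return k / k.max()


@dataclass
class GroundTruth:
    """Generative parameters of a simulated population.

    Arrays are length N (neurons) except ``cue_tuning`` (N x 6).  Gains are
    rate amplitudes in events/s at the kernel peak.
    """

    baseline_rate: np.ndarray
    cue_gain: np.ndarray
    cue_tuning: np.ndarray
    lick_gain: np.ndarray
    reward_gain: np.ndarray
    history_gain: np.ndarray
    #: per-neuron kernel mixture, shape (N, n_bumps, 2): (weight, peak s)
    cue_kernel_params: np.ndarray | None = None
    noise_model: str = "poisson_spikes"  # or "gaussian_trace"
    trace_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.cue_kernel_params is None:
            n = self.baseline_rate.size
            self.cue_kernel_params = np.tile([[1.0, 0.4], [0.0, 1.0]],
                                             (n, 1, 1))

    def cue_kernel(self, neuron: int, dt: float = DT) -> np.ndarray:
        return mixed_cue_kernel(self.cue_kernel_params[neuron], dt=dt)

    @property
    def n_neurons(self) -> int:
        return self.baseline_rate.size

    def labels(self) -> list[str]:
        """Deterministic generative label per neuron."""
        out = []
        for i in range(self.n_neurons):
            if self.cue_gain[i] > 0 and self.history_gain[i] > 0:
                out.append("history")
            elif self.cue_gain[i] > 0 and np.allclose(self.cue_tuning[i], RANKED_TUNING):
                out.append("value")
            elif self.cue_gain[i] > 0 and np.allclose(self.cue_tuning[i], UNTUNED_TUNING):
                out.append("untuned")
            elif self.cue_gain[i] > 0:
                out.append("cue_other")
            elif self.lick_gain[i] > 0:
                out.append("lick")
            elif self.reward_gain[i] > 0:
                out.append("reward")
            else:
                out.append("none")
        return out


def make_population(n_value: int = 0, n_untuned: int = 0, n_lick: int = 0,
                    n_reward: int = 0, n_history: int = 0, n_none: int = 0,
                    n_cue_other: int = 0, seed: int = 0,
                    baseline_range: tuple[float, float] = (2.0, 8.0),
                    cue_gain: float = 10.0, lick_gain: float = 5.0,
                    reward_gain: float = 10.0,
                    noise_model: str = "poisson_spikes") -> GroundTruth:
    """Assemble a population with the standard cell classes.

    ``cue_gain`` of 10 events/s at the kernel peak over a 2-8 events/s
    baseline is the reference signal-to-noise level used throughout the
    recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = n_value + n_untuned + n_lick + n_reward + n_history + n_none + n_cue_other
    baseline = rng.uniform(*baseline_range, n)
    cg = np.zeros(n)
    lg = np.zeros(n)
    rg = np.zeros(n)
    hg = np.zeros(n)
    tuning = np.tile(RANKED_TUNING, (n, 1))
    i = 0
    for _ in range(n_value):
        cg[i] = cue_gain; i += 1
    for _ in range(n_untuned):
        cg[i] = cue_gain; tuning[i] = UNTUNED_TUNING; i += 1
    for _ in range(n_lick):
        lg[i] = lick_gain; i += 1
    for _ in range(n_reward):
        rg[i] = reward_gain; i += 1
    for _ in range(n_history):
        cg[i] = cue_gain; hg[i] = 1.0; i += 1
    i += n_none
    for _ in range(n_cue_other):
        cg[i] = cue_gain
        tuning[i] = RANKED_TUNING[rng.permutation(6)]
        i += 1
    # neuron-specific response shapes: two gamma bumps, random weights
    params = np.empty((n, 2, 2))
    params[:, 0, 0] = 1.0
    params[:, 0, 1] = rng.uniform(0.2, 1.0, n)    # early bump peak
    params[:, 1, 0] = rng.uniform(0.0, 0.9, n)    # late bump weight
    params[:, 1, 1] = rng.uniform(0.8, 2.2, n)    # late bump peak
    return GroundTruth(baseline_rate=baseline, cue_gain=cg, cue_tuning=tuning,
                       lick_gain=lg, reward_gain=rg, history_gain=hg,
                       cue_kernel_params=params, noise_model=noise_model)


def _add_events(rate: np.ndarray, times: np.ndarray, kernel: np.ndarray,
                gains: np.ndarray | float, dt: float = DT) -> None:
    """Add gain-scaled copies of ``kernel`` starting at each event time."""
    gains = np.broadcast_to(np.asarray(gains, dtype=float), times.shape)
    n = rate.size
    for t, g in zip(times, gains):
        if g == 0.0:
            continue
        i0 = int(round(t / dt))
        if i0 >= n:
            continue
        i1 = min(i0 + kernel.size, n)
        rate[i0:i1] += g * kernel[: i1 - i0]


def neuron_rate(trials: pd.DataFrame, events: EventLog, truth: GroundTruth,
                neuron: int, session_end: float, dt: float = DT) -> np.ndarray:
    """Rectified instantaneous rate of one neuron on the 1 ms grid."""
    n_bins = int(np.ceil(session_end / dt))
    rate = np.full(n_bins, truth.baseline_rate[neuron])
    if truth.cue_gain[neuron] > 0:
        tun = truth.cue_tuning[neuron][trials["cue_index"].to_numpy()]
        h = truth.history_gain[neuron]
        if h > 0:
            # shift the static tuning toward the generative trial value
            nominal = trials["cue_value"].to_numpy()
            s = tun + h * (trials["trial_value"].to_numpy() - nominal)
        else:
            s = tun
        _add_events(rate, trials["cue_onset"].to_numpy(),
                    truth.cue_kernel(neuron, dt),
                    truth.cue_gain[neuron] * np.clip(s, 0, None), dt)
    if truth.lick_gain[neuron] > 0:
        _add_events(rate, events.lick_times, lick_kernel_shape(dt=dt),
                    truth.lick_gain[neuron], dt)
    if truth.reward_gain[neuron] > 0:
        _add_events(rate, events.reward_consumption_onsets,
                    reward_kernel_shape(dt=dt), truth.reward_gain[neuron], dt)
    return np.clip(rate, 0.0, None)


def generate_population(trials: pd.DataFrame, events: EventLog,
                        truth: GroundTruth, seed: int = 0,
                        session_end: float | None = None,
                        dt: float = DT) -> list[np.ndarray]:
    """Draw spike trains (list of sorted spike-time arrays, one per neuron).

    Spike counts are Poisson in ``dt`` bins of the rectified rate; spikes are
    placed uniformly within their bin.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if session_end is None:
        session_end = float(trials["cue_onset"].iloc[-1]) + 10.0
    spikes = []
    for i in range(truth.n_neurons):
        rate = neuron_rate(trials, events, truth, i, session_end, dt)
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(counts.size), counts)
        t = (idx + rng.uniform(0, 1, idx.size)) * dt
        spikes.append(np.sort(t))
    return spikes


def generate_traces(trials: pd.DataFrame, events: EventLog, truth: GroundTruth,
                    seed: int = 0, session_end: float | None = None,
                    fs: float = 15.0) -> np.ndarray:
    """Deconvolved-calcium-like traces: rate sampled at ``fs`` plus noise.

    Returns a (T, N) matrix in events/s units.
    """
    rng = np.random.default_rng(seed)
    if session_end is None:
        session_end = float(trials["cue_onset"].iloc[-1]) + 10.0
    n_frames = int(np.floor(session_end * fs))
    frame_idx = (np.arange(n_frames) / fs / DT).astype(int)
    out = np.empty((n_frames, truth.n_neurons))
    for i in range(truth.n_neurons):
        rate = neuron_rate(trials, events, truth, i, session_end)
        out[:, i] = rate[frame_idx] + rng.normal(0, truth.trace_noise_sd, n_frames)
    return out


@dataclass
class Session:
    """A complete simulated session: task, behavior, ground truth, spikes."""

    config: TaskConfig
    trials: pd.DataFrame
    events: EventLog
    truth: GroundTruth
    spikes: list[np.ndarray] = field(default_factory=list)

    @property
    def session_end(self) -> float:
        return float(self.trials["cue_onset"].iloc[-1]) + 10.0


def simulate_session(config: TaskConfig, truth: GroundTruth,
                     neural_seed: int | None = None) -> Session:
    """Generate task, behavior, and spikes in one call."""
    trials, events = generate_task(config)
    if neural_seed is None:
        neural_seed = config.seed + 10_000
    spikes = generate_population(trials, events, truth, seed=neural_seed)
    return Session(config=config, trials=trials, events=events, truth=truth,
                   spikes=spikes)
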