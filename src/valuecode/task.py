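"""Task structure and behavior for a six-odor Pavlovian conditioning session.

Three odors per set predict reward with probability 1 (CS+), 0.5 (CS50), or
0 (CS-).  Electrophysiology-style sessions interleave two odor sets in
alternating blocks; imaging-style sessions run one set per day.  Licking is
generated as an inhomogeneous Poisson process whose anticipatory component
ramps from cue onset to reward time with amplitude proportional to the
trial's generative value (cue value plus an exponentially decaying same-cue
reward-history term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Cue labels in canonical order (odor set A then B, descending reward prob).
CUE_LABELS = ("A+", "A50", "A-", "B+", "B50", "B-")
#: Reward probability per canonical cue.
CUE_REWARD_PROBS = (1.0, 0.5, 0.0, 1.0, 0.5, 0.0)
#: Nominal cue value (ranked by reward probability).
CUE_VALUES = (1.0, 0.5, 0.0, 1.0, 0.5, 0.0)

#: Minimum interlick interval: the lick sensor cannot resolve more than 12
#: licks per second, i.e. intervals below 1/12 s (~0.083 s) are discarded.
MIN_INTERLICK_INTERVAL = 1.0 / 12.0

#: A lick preceded by at least this much silence opens a lick bout.
BOUT_GAP = 0.5


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one conditioning session.

    Defaults reproduce an electrophysiology-style session: six blocks of 51
    trials, alternating odor sets, rewards delivered 2.5 s after odor onset
    on CS+ and on exactly half (rounded up) of CS50 trials.
    """

    n_cues_per_set: int = 3
    n_sets: int = 2
    reward_probs: tuple[float, float, float] = (1.0, 0.5, 0.0)
    trials_per_block: int = 51
    n_blocks: int = 6
    iti_range: tuple[float, float] = (8.0, 12.0)
    odor_duration: float = 1.5
    reward_delay: float = 2.5
    layout: str = "blocked"  # "blocked" | "per_day"
    seed: int = 0
    # behavior generation
    lick_baseline_rate: float = 0.3     # licks/s outside task epochs
    lick_ramp_peak: float = 7.0         # licks/s at reward time for value 1
    consum_rate: float = 7.0            # licks/s during reward consumption
    consum_duration: float = 2.0        # s of consummatory licking
    history_weight: float = 0.0         # weight of same-cue history on value
    history_tau: float = 3.0            # trials; decay of the history term
    history_depth: int = 10             # same-cue outcomes entering the term

    def __post_init__(self) -> None:
        if self.n_cues_per_set <= 0 or self.n_sets not in (1, 2):
            raise ValueError("need n_cues_per_set > 0 and n_sets in {1, 2}")
        if self.trials_per_block <= 0 or self.n_blocks <= 0:
            raise ValueError("counts must be positive")
        if tuple(sorted(self.reward_probs, reverse=True)) != (1.0, 0.5, 0.0):
            raise ValueError("reward_probs must be exactly {1.0, 0.5, 0.0}")
        if self.iti_range[0] < 7.5:
            raise ValueError(
                "iti_range lower bound below 7.5 s: per-trial analysis "
                "windows (-1 to 6.5 s) would overlap"
            )
        if self.iti_range[1] < self.iti_range[0]:
            raise ValueError("iti_range must be (low, high) with low <= high")
        if self.layout not in ("blocked", "per_day"):
            raise ValueError("layout must be 'blocked' or 'per_day'")

    @property
    def n_cues(self) -> int:
        return self.n_cues_per_set * self.n_sets

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.n_blocks


@dataclass
class EventLog:
    """Behavioral events of one session (all times in seconds)."""

    lick_times: np.ndarray
    bout_starts: np.ndarray
    reward_times: np.ndarray                # valve openings (rewarded trials)
    reward_consumption_onsets: np.ndarray   # first lick after each reward


def debounce_licks(times: np.ndarray,
                   min_interval: float = MIN_INTERLICK_INTERVAL) -> np.ndarray:
    """Drop licks closer than ``min_interval`` to the last retained lick.

    Greedy from the first lick, mirroring how interlick intervals are
    thresholded by the detector; caps the detectable rate at 12 licks/s.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_interval:
            kept.append(t)
    return np.asarray(kept)


def find_bout_starts(lick_times: np.ndarray, gap: float = BOUT_GAP) -> np.ndarray:
    if lick_times.size == 0:
        return lick_times
    isi = np.diff(lick_times)
    starts = np.concatenate(([True], isi >= gap))
    return lick_times[starts]


def _cue_sequence(config: TaskConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (cue_index per trial, block_index per trial), cue index canonical."""
    cues, blocks = [], []
    for b in range(config.n_blocks):
        if config.layout == "blocked" and config.n_sets == 2:
            odor_set = b % 2  # alternating odor sets across blocks
        else:
            odor_set = 0
        base = odor_set * config.n_cues_per_set
        per_cue, extra = divmod(config.trials_per_block, config.n_cues_per_set)
        block_cues = np.repeat(np.arange(config.n_cues_per_set), per_cue)
        if extra:
            block_cues = np.concatenate(
                [block_cues, rng.choice(config.n_cues_per_set, extra, replace=False)])
        rng.shuffle(block_cues)
        cues.append(base + block_cues)
        blocks.append(np.full(block_cues.size, b + 1))
    return np.concatenate(cues), np.concatenate(blocks)


def _assign_rewards(cue_idx: np.ndarray, config: TaskConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """CS+ always rewarded, CS- never; CS50 on an exact-half schedule."""
    rewarded = np.zeros(cue_idx.size, dtype=bool)
    for c in range(config.n_cues):
        p = CUE_REWARD_PROBS[c]
        sel = np.flatnonzero(cue_idx == c)
        if p == 1.0:
            rewarded[sel] = True
        elif p == 0.5:
            n_rew = (sel.size + 1) // 2
            rewarded[sel[rng.permutation(sel.size)[:n_rew]]] = True
    return rewarded


def trial_values(cue_idx: np.ndarray, rewarded: np.ndarray,
                 config: TaskConfig) -> np.ndarray:
    """Generative per-trial value: cue value plus a same-cue history term.

    The history term is a weighted sum of centered outcomes (reward minus
    the cue's reward probability) on the previous `history_depth` trials of
    the same cue, with exponential decay `exp(-lag/history_tau)`.  With
    history_weight = 0 the value is exactly the nominal cue value.  Values
    are clipped at 0 so they remain valid kernel scalings.
    """
    v = np.array([CUE_VALUES[c] for c in cue_idx], dtype=float)
    if config.history_weight != 0.0:
        for c in np.unique(cue_idx):
            sel = np.flatnonzero(cue_idx == c)
            outcomes = rewarded[sel].astype(float) - CUE_REWARD_PROBS[c]
            for j, t in enumerate(sel):
                lags = np.arange(1, min(j, config.history_depth) + 1)
                if lags.size:
                    past = outcomes[j - lags]
                    w = np.exp(-(lags - 1) / config.history_tau)
                    v[t] += config.history_weight * float(past @ w)
    return np.clip(v, 0.0, None)


def _poisson_times(rate_fn, t0: float, t1: float, rate_max: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson event times on [t0, t1) by thinning."""
    n = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    keep = rng.uniform(0, rate_max, n) < rate_fn(cand)
    return cand[keep]


def generate_task(config: TaskConfig) -> tuple[pd.DataFrame, EventLog]:
    """Generate the trial table and behavioral event log for one session.

    Returns a trial table (one row per trial: cue, reward, onset, block,
    generative trial value) and an :class:`EventLog` with debounced lick
    times, bout starts, and reward consumption onsets.  Fully deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cue_idx, block_idx = _cue_sequence(config, rng)
    rewarded = _assign_rewards(cue_idx, config, rng)
    n = cue_idx.size
    itis = rng.uniform(config.iti_range[0], config.iti_range[1], n)
    onsets = 10.0 + np.cumsum(itis) - itis[0]
    v_t = trial_values(cue_idx, rewarded, config)

    trials = pd.DataFrame({
        "trial_index": np.arange(n),
        "cue_id": [CUE_LABELS[c] for c in cue_idx],
        "cue_index": cue_idx,
        "reward_prob": [CUE_REWARD_PROBS[c] for c in cue_idx],
        "cue_value": [CUE_VALUES[c] for c in cue_idx],
        "rewarded": rewarded,
        "cue_onset": onsets,
        "block_index": block_idx,
        "trial_value": v_t,
    })

    session_end = onsets[-1] + 10.0
    reward_times = onsets[rewarded] + config.reward_delay

    def lick_rate(t: np.ndarray) -> np.ndarray:
        rate = np.full(t.shape, config.lick_baseline_rate)
        # anticipatory ramp: 0 at cue onset, g*v_t at reward time
        idx = np.searchsorted(onsets, t, side="right") - 1
        idx = np.clip(idx, 0, n - 1)
        dt = t - onsets[idx]
        in_antic = (dt >= 0) & (dt < config.reward_delay)
        rate[in_antic] += (config.lick_ramp_peak * v_t[idx[in_antic]]
                           * dt[in_antic] / config.reward_delay)
        return rate

    rate_max = config.lick_baseline_rate + config.lick_ramp_peak * max(
        1.0, float(v_t.max()) if n else 1.0)
    licks = _poisson_times(lick_rate, 0.0, session_end, rate_max, rng)

    # consummatory licking: a guaranteed first lick shortly after each
    # reward, then a burst at consum_rate
    consum = []
    for rt in reward_times:
        first = rt + rng.uniform(0.08, 0.25)
        burst = _poisson_times(lambda t: np.full(t.shape, config.consum_rate),
                               first, rt + config.consum_duration,
                               config.consum_rate, rng)
        consum.append(np.concatenate(([first], burst)))
    if consum:
        licks = np.sort(np.concatenate([licks] + consum))

    licks = debounce_licks(licks)
    consumption_onsets = np.array(
        [licks[np.searchsorted(licks, rt)] for rt in reward_times
         if np.searchsorted(licks, rt) < licks.size])

    events = EventLog(
        lick_times=licks,
        bout_starts=find_bout_starts(licks),
        reward_times=reward_times,
        reward_consumption_onsets=consumption_onsets,
    )
    return trials, events
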