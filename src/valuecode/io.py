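"""Serialization: sessions to HDF5, tables to TSV, configs to YAML."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import pandas as pd
import yaml

from .simulate import GroundTruth, Session
from .task import EventLog, TaskConfig


def save_config(config: TaskConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh)


def load_config(path: str | Path) -> TaskConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("reward_probs", "iti_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return TaskConfig(**raw)


def save_trials_tsv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def save_events_tsv(events: EventLog, path: str | Path) -> None:
    rows = ([("lick", t) for t in events.lick_times]
            + [("bout_start", t) for t in events.bout_starts]
            + [("reward", t) for t in events.reward_times]
            + [("consumption", t) for t in events.reward_consumption_onsets])
    pd.DataFrame(rows, columns=["event", "time"]).sort_values("time").to_csv(
        path, sep="\t", index=False)


def save_session_h5(session: Session, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = yaml.safe_dump(asdict(session.config))
        tg = f.create_group("trials")
        for col in session.trials.columns:
            data = session.trials[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            tg.create_dataset(col, data=data)
        eg = f.create_group("events")
        eg.create_dataset("lick_times", data=session.events.lick_times)
        eg.create_dataset("bout_starts", data=session.events.bout_starts)
        eg.create_dataset("reward_times", data=session.events.reward_times)
        eg.create_dataset("reward_consumption_onsets",
                          data=session.events.reward_consumption_onsets)
        gg = f.create_group("ground_truth")
        for name in ("baseline_rate", "cue_gain", "cue_tuning", "lick_gain",
                     "reward_gain", "history_gain", "cue_kernel_params"):
            gg.create_dataset(name, data=getattr(session.truth, name))
        gg.attrs["noise_model"] = session.truth.noise_model
        sg = f.create_group("spikes")
        for i, st in enumerate(session.spikes):
            sg.create_dataset(str(i), data=st)


def load_session_h5(path: str | Path) -> Session:
    with h5py.File(path, "r") as f:
        config = load_config_from_string(f.attrs["config"])
        cols = {}
        for col in f["trials"]:
            data = f["trials"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        trials = pd.DataFrame(cols).sort_values("trial_index").reset_index(drop=True)
        ev = f["events"]
        events = EventLog(
            lick_times=ev["lick_times"][()],
            bout_starts=ev["bout_starts"][()],
            reward_times=ev["reward_times"][()],
            reward_consumption_onsets=ev["reward_consumption_onsets"][()],
        )
        gg = f["ground_truth"]
        truth = GroundTruth(
            baseline_rate=gg["baseline_rate"][()],
            cue_gain=gg["cue_gain"][()],
            cue_tuning=gg["cue_tuning"][()],
            lick_gain=gg["lick_gain"][()],
            reward_gain=gg["reward_gain"][()],
            history_gain=gg["history_gain"][()],
            cue_kernel_params=gg["cue_kernel_params"][()],
            noise_model=gg.attrs["noise_model"],
        )
        spikes = [f["spikes"][str(i)][()] for i in range(len(f["spikes"]))]
    return Session(config=config, trials=trials, events=events, truth=truth,
                   spikes=spikes)


def load_config_from_string(text: str) -> TaskConfig:
    raw = yaml.safe_load(text)
    for key in ("reward_probs", "iti_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return TaskConfig(**raw)
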