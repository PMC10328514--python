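"""End-to-end orchestration of the analysis stages on one session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as design_mod
from . import glm, psth, trialvalue, tuning
from .design import (DesignMatrix, assemble_full_design,
                     assemble_restricted_design)
from .psth import BinnedActivity, PsthTensor
from .simulate import Session
from .task import EventLog


@dataclass
class PreparedSession:
    """Binned, z-scored activity and designs derived from raw session data."""

    trials: pd.DataFrame
    events: EventLog
    activity: BinnedActivity          # 0.02 s smoothed rates, z-scored
    full_design: DesignMatrix
    restricted_design: DesignMatrix
    F_full: np.ndarray                # z-scored rates on full-design rows
    F_restricted: np.ndarray          # ... on restricted-design rows
    session_end: float

    def psth(self, window=(-1.0, 6.5), trial_filter="all") -> PsthTensor:
        return psth.make_psth(self.activity, self.trials, window,
                              trial_filter=trial_filter)

    def aligned(self, window=(-1.0, 2.5), trial_mask=None) -> np.ndarray:
        """(trials, bins, neurons) z-scored traces at 0.1 s bins."""
        trials = self.trials if trial_mask is None else self.trials[trial_mask]
        return psth.align_trials(self.activity,
                                 trials["cue_onset"].to_numpy(), window)


def _rows_activity(activity: BinnedActivity, design: DesignMatrix) -> np.ndarray:
    """Activity sampled on a design's rows (mean-rate 0.1 s bins)."""
    coarse = psth.rebin(activity, design_mod.DESIGN_BIN)
    row_bins = np.floor(design.segments.row_times()
                        / design_mod.DESIGN_BIN + 1e-9).astype(int)
    return coarse.values[row_bins]


def prepare_session(session: Session) -> PreparedSession:
    """Bin, smooth, z-score, and build both design matrices."""
    end = session.session_end
    act = psth.bin_and_smooth_spikes(session.spikes, end)
    act = psth.zscore_to_baseline(act, trials=session.trials)
    full = assemble_full_design(session.trials, session.events, end)
    restricted = assemble_restricted_design(session.trials, session.events, end)
    return PreparedSession(
        trials=session.trials, events=session.events, activity=act,
        full_design=full, restricted_design=restricted,
        F_full=_rows_activity(act, full),
        F_restricted=_rows_activity(act, restricted),
        session_end=end,
    )


@dataclass
class SessionAnalysis:
    """Collected stage outputs for one session."""

    prepared: PreparedSession
    full_table: glm.UniqueVarianceTable | None = None
    full_labels: list[set[str]] | None = None
    restricted_table: glm.UniqueVarianceTable | None = None
    restricted_labels: list[set[str]] | None = None
    cue_only: np.ndarray | None = None
    assignments: list[tuning.BestModelAssignment] | None = None
    trial_value: trialvalue.TrialValueFit | None = None


def run_glm(prep: PreparedSession, which: str = "full", r: int = 20,
            fold_seed: int = 0) -> tuple[glm.UniqueVarianceTable, list[set[str]]]:
    design = prep.full_design if which == "full" else prep.restricted_design
    F = prep.F_full if which == "full" else prep.F_restricted
    groups = ("cues", "licks", "reward") if which == "full" else ("cues", "licks")
    table, _ = glm.unique_variance(design, F, prep.trials, groups=groups,
                                   r=r, fold_seed=fold_seed)
    return table, glm.classify_coding(table)


def run_cue_models(prep: PreparedSession, labels: list[set[str]],
                   n_null: int = 1000, seed: int = 0
                   ) -> tuple[np.ndarray, list[tuning.BestModelAssignment]]:
    cue_only = np.flatnonzero(tuning.identify_cue_only_neurons(labels))
    if cue_only.size == 0:
        return cue_only, []
    fitter = tuning.ScaledCueFitter(prep.trials, prep.F_restricted,
                                    fold_seed=seed)
    assignments = tuning.classify_cue_neurons(fitter, cue_only,
                                              n_null=n_null, seed=seed)
    return cue_only, assignments


def run_session_analysis(session: Session, n_null: int = 200,
                         seed: int = 0) -> SessionAnalysis:
    """The standard single-session pipeline: GLM classification on both
    designs, cue-tuning models for cue-only neurons, and the trial-value
    model."""
    prep = prepare_session(session)
    out = SessionAnalysis(prepared=prep)
    out.full_table, out.full_labels = run_glm(prep, "full", fold_seed=seed)
    out.restricted_table, out.restricted_labels = run_glm(
        prep, "restricted", fold_seed=seed)
    out.cue_only, out.assignments = run_cue_models(
        prep, out.restricted_labels, n_null=n_null, seed=seed)
    out.trial_value = trialvalue.fit_trial_value_model(
        [(session.trials, session.events)])
    return out
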