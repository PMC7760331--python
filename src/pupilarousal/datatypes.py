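"""Shared containers for traces, trials, subjects and derived measures.

All pipeline stages exchange these light dataclasses; heavy tabular results
use pandas DataFrames instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CONDITIONS = ("reward", "neutral", "control")
RESPONSE_CONDITIONS = ("reward", "neutral")

#: QC status codes for a trial.
KEPT = "kept"
DISCARDED_GAZE = "discarded_gaze"
DISCARDED_INTERPOLATION = "discarded_interpolation"


class ConfigError(ValueError):
    """Raised for invalid or infeasible configuration."""


@dataclass
class PupilTrace:
    """One trial's eye-tracker time series.

    ``time`` is in seconds relative to cue onset (the baseline period has
    negative times), on a uniform grid at the run's sampling rate. ``pupil``
    is in arbitrary recorder units until :func:`~pupilarousal.preprocess.zscore_run`
    converts the run to z-units. Samples with ``valid == False`` carry no
    usable pupil value (blinks / eye closure).
    """

    time: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray
    condition: str
    trial_index: int  # 1-based ordinal within its condition
    interpolated: np.ndarray = None
    usable: bool = True

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.time), dtype=bool)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            time=self.time.copy(), pupil=self.pupil.copy(),
            gaze_x=self.gaze_x.copy(), gaze_y=self.gaze_y.copy(),
            valid=self.valid.copy(), condition=self.condition,
            trial_index=self.trial_index,
            interpolated=self.interpolated.copy(), usable=self.usable)


@dataclass
class TrialRecord:
    """Behavioral and QC bookkeeping for one trial."""

    condition: str
    trial_index: int
    rt: float = np.nan  # seconds; NaN for the no-response control condition
    success: Optional[bool] = None
    qc_status: str = KEPT
    qc_reason: str = ""


@dataclass
class ClinicalScores:
    """Interview-derived clinical covariates for one subject."""

    symptom_count: int  # depressive symptoms in the past 2 weeks, 0-9
    symptom_impact: int  # ordinal 0-10
    anhedonia: float  # continuous >= 0
    age: float
    sex: str  # "f" / "m"
    group: str  # "control" / "depressed"

    @property
    def acute_flag(self) -> bool:
        """Five or more current depressive symptoms."""
        return self.symptom_count >= 5

    def __post_init__(self) -> None:
        if self.group == "control" and self.symptom_count > 3:
            raise ConfigError("controls must have symptom_count <= 3")


@dataclass
class SubjectDataset:
    """All traces and trials of one subject-run plus clinical scores."""

    subject_id: str
    clinical: ClinicalScores
    traces: list  # list[PupilTrace], run order
    trials: list  # list[TrialRecord], run order


@dataclass
class GazeWindow:
    """Rectangular fixation window centered on (cx, cy)."""

    cx: float
    cy: float
    half_width: float
    half_height: float

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.half_height <= 0:
            raise ConfigError("gaze window must have positive area")

    def outside(self, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
        return (np.abs(gx - self.cx) > self.half_width) | (
            np.abs(gy - self.cy) > self.half_height)


@dataclass
class QCReport:
    """Run- and trial-level quality control outcome for one subject-run."""

    run_missing_fraction: float
    run_excluded: bool
    trial_status: list = field(default_factory=list)  # (condition, trial_index, status, reason)
    discarded_fraction: float = 0.0


@dataclass
class DerivedMeasures:
    """Per-subject summary scores over the anticipation window."""

    mean_size: dict  # condition -> z-units
    mean_dilation: dict  # condition -> z-units/s
    diff_reward_minus_neutral: float
    diff_reward_minus_control: float
    median_rt: dict  # response condition -> seconds
    n_kept: dict  # condition -> kept trial count
    missing_conditions: tuple = ()


__all__ = [
    "CONDITIONS", "RESPONSE_CONDITIONS", "KEPT", "DISCARDED_GAZE",
    "DISCARDED_INTERPOLATION", "ConfigError", "PupilTrace", "TrialRecord",
    "ClinicalScores", "SubjectDataset", "GazeWindow", "QCReport",
    "DerivedMeasures", "replace",
]
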