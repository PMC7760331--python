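"""Pupillometry preprocessing: blink interpolation, QC, z-scoring, dilation.

The pipeline applied to every subject-run is:

1. run-level QC — exclude the run when more than 15% of its pupil samples
   are missing (blinks / eye closure), computed before any interpolation;
2. linear interpolation across blink gaps (edge gaps extended with the
   nearest valid value);
3. trial-level QC — discard trials whose gaze left the fixation window for a
   contiguous episode longer than 1 s, and trials with more than 50%
   interpolated samples;
4. z-transform of the pupil signal, pooled over all kept samples of the run;
5. dilation = first difference of size divided by the sampling interval;
6. per-subject summaries: per-condition means of window-averaged size and
   dilation over the 0–6 s anticipation window, differential scores, and
   median response times.

All thresholds are strict ("more than") and the averaging window is closed
at both ends.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (CONDITIONS, DISCARDED_GAZE, DISCARDED_INTERPOLATION,
                        KEPT, RESPONSE_CONDITIONS, ConfigError,
                        DerivedMeasures, GazeWindow, PupilTrace, QCReport,
                        SubjectDataset, TrialRecord)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable QC and scoring settings (defaults follow the documented rules)."""

    run_missing_threshold: float = 0.15
    gaze_half_width: float = 150.0  # px; fixation window half-extent
    gaze_half_height: float = 150.0
    max_outside_s: float = 1.0
    max_interp_frac: float = 0.5
    cumulative_gaze: bool = False  # count total (not contiguous) time outside
    window: tuple = (0.0, 6.0)  # averaging window, closed at both ends


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def interpolate_blinks(trace: PupilTrace) -> PupilTrace:
    """Fill invalid pupil samples by linear interpolation between valid ones.

    Interior gaps get the straight line between their nearest valid
    neighbours; leading/trailing gaps are filled with the nearest valid value.
    A trace without a single valid sample is returned marked unusable.
    """
    out = trace.copy()
    good = out.valid & np.isfinite(out.pupil)
    if not good.any():
        out.usable = False
        out.interpolated = np.ones(len(out.time), dtype=bool)
        return out
    bad = ~good
    if bad.any():
        out.pupil[bad] = np.interp(out.time[bad], out.time[good],
                                   out.pupil[good])
    out.interpolated = bad
    return out


def run_missing_fraction(traces: list) -> float:
    """Fraction of invalid pupil samples across the whole run (pre-interpolation)."""
    if not traces:
        raise ValueError("empty run")
    total = sum(len(t.time) for t in traces)
    missing = sum(int((~(t.valid & np.isfinite(t.pupil))).sum()) for t in traces)
    return missing / total


def qc_run(traces: list, threshold: float = 0.15) -> QCReport:
    """Run-level exclusion: strictly more than ``threshold`` missing samples."""
    frac = run_missing_fraction(traces)
    return QCReport(run_missing_fraction=frac, run_excluded=frac > threshold)


def gaze_window_for_run(traces: list, params: PreprocessParams) -> GazeWindow:
    """Fixation window centered on the subject's median gaze over the run."""
    gx = np.concatenate([t.gaze_x for t in traces])
    gy = np.concatenate([t.gaze_y for t in traces])
    return GazeWindow(cx=float(np.median(gx)), cy=float(np.median(gy)),
                      half_width=params.gaze_half_width,
                      half_height=params.gaze_half_height)


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def qc_trial(trace: PupilTrace, window: GazeWindow,
             max_outside: float = 1.0, max_interp: float = 0.5,
             cumulative: bool = False) -> tuple:
    """Trial-level QC; returns ``(status, reason)``.

    A trial is discarded when gaze stayed outside the fixation window for
    strictly more than ``max_outside`` seconds (one contiguous episode by
    default, total time when ``cumulative``), or when strictly more than
    ``max_interp`` of its samples are interpolated.
    """
    if window.half_width <= 0 or window.half_height <= 0:
        raise ConfigError("degenerate gaze window")
    rate = trace.sampling_rate
    outside = window.outside(trace.gaze_x, trace.gaze_y)
    n_outside = (int(outside.sum()) if cumulative
                 else _longest_true_run(outside))
    # compare in sample counts so the boundary (exactly max_outside seconds)
    # is not broken by floating-point reconstruction of the sampling rate
    if n_outside > int(round(max_outside * rate)):
        return DISCARDED_GAZE, (f"gaze outside window for "
                                f"{n_outside / rate:.3f} s")
    if not trace.usable:
        return DISCARDED_INTERPOLATION, "no valid samples in trace"
    interp_frac = float(trace.interpolated.mean())
    if interp_frac > max_interp:
        return DISCARDED_INTERPOLATION, f"{interp_frac:.1%} samples interpolated"
    return KEPT, ""


def zscore_run(traces: list) -> list:
    """Z-transform pupil values, pooled over all samples of the given traces.

    The same affine transform is applied to every sample, so the pooled mean
    is 0 and the pooled SD 1 afterwards.  A constant run raises ValueError.
    """
    if not traces:
        raise ValueError("empty run")
    pooled = np.concatenate([t.pupil for t in traces])
    mu = float(pooled.mean())
    sd = float(pooled.std())
    if sd < 1e-12:
        raise ValueError("zero variance: cannot z-score a constant run")
    out = []
    for t in traces:
        t = t.copy()
        t.pupil = (t.pupil - mu) / sd
        out.append(t)
    return out


def compute_dilation(trace: PupilTrace) -> np.ndarray:
    """Dilation series: first difference of pupil size / sampling interval.

    Element ``i`` covers the interval [time[i], time[i+1]]; the series is one
    sample shorter than the input.
    """
    if len(trace.time) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(trace.pupil) * trace.sampling_rate


def window_mean_size(trace: PupilTrace, window: tuple = (0.0, 6.0)) -> float:
    sel = (trace.time >= window[0]) & (trace.time <= window[1])
    return float(trace.pupil[sel].mean())


def window_mean_dilation(trace: PupilTrace, window: tuple = (0.0, 6.0)) -> float:
    """Mean of the dilation series over the window.

    Uses the intervals whose both endpoints fall inside the (closed) window;
    by the telescoping identity this equals
    (pupil at window end - pupil at window start) / covered duration.
    """
    d = compute_dilation(trace)
    sel = (trace.time[:-1] >= window[0]) & (trace.time[1:] <= window[1])
    if not sel.any():
        raise ValueError("averaging window contains no dilation interval")
    return float(d[sel].mean())


def summarize_subject(traces: list, records: list,
                      window: tuple = (0.0, 6.0)) -> DerivedMeasures:
    """Per-subject summary over kept trials.

    Size and dilation are trial means of window averages per condition;
    median RTs pool successful and failed response trials (RT is behavioral
    and does not depend on pupil QC).  A condition without kept trials is
    flagged missing (NaN measures).
    """
    status = {(r.condition, r.trial_index): r.qc_status for r in records}
    mean_size, mean_dil, n_kept = {}, {}, {}
    missing = []
    for cond in CONDITIONS:
        kept = [t for t in traces
                if t.condition == cond
                and status.get((t.condition, t.trial_index), KEPT) == KEPT]
        n_kept[cond] = len(kept)
        if not kept:
            mean_size[cond] = np.nan
            mean_dil[cond] = np.nan
            missing.append(cond)
            continue
        mean_size[cond] = float(np.mean([window_mean_size(t, window) for t in kept]))
        mean_dil[cond] = float(np.mean([window_mean_dilation(t, window) for t in kept]))
    if missing:
        log.warning("conditions without kept trials: %s", missing)
    median_rt = {}
    for cond in RESPONSE_CONDITIONS:
        rts = [r.rt for r in records if r.condition == cond and np.isfinite(r.rt)]
        median_rt[cond] = float(np.median(rts)) if rts else np.nan
    return DerivedMeasures(
        mean_size=mean_size, mean_dilation=mean_dil,
        diff_reward_minus_neutral=mean_dil["reward"] - mean_dil["neutral"],
        diff_reward_minus_control=mean_dil["reward"] - mean_dil["control"],
        median_rt=median_rt, n_kept=n_kept, missing_conditions=tuple(missing))


# ---------------------------------------------------------------------------
# Subject- and cohort-level drivers
# ---------------------------------------------------------------------------

def preprocess_subject(ds: SubjectDataset,
                       params: PreprocessParams = PreprocessParams()) -> tuple:
    """Full preprocessing of one subject-run.

    Returns ``(derived, qc_report, traces_z)``; ``derived`` and ``traces_z``
    are None when the run fails run-level QC.  Trial QC statuses are written
    back onto the subject's :class:`TrialRecord` list.
    """
    report = qc_run(ds.traces, params.run_missing_threshold)
    if report.run_excluded:
        log.info("%s: run excluded (%.1f%% missing)", ds.subject_id,
                 100 * report.run_missing_fraction)
        return None, report, None

    interp = [interpolate_blinks(t) for t in ds.traces]
    window = gaze_window_for_run(interp, params)
    rec_by_key = {(r.condition, r.trial_index): r for r in ds.trials}
    kept_traces = []
    for t in interp:
        status, reason = qc_trial(t, window, params.max_outside_s,
                                  params.max_interp_frac,
                                  params.cumulative_gaze)
        rec = rec_by_key[(t.condition, t.trial_index)]
        rec.qc_status, rec.qc_reason = status, reason
        report.trial_status.append((t.condition, t.trial_index, status, reason))
        if status == KEPT:
            kept_traces.append(t)
    n_trials = len(interp)
    report.discarded_fraction = (n_trials - len(kept_traces)) / n_trials

    traces_z = zscore_run(kept_traces) if kept_traces else []
    derived = summarize_subject(traces_z, ds.trials, params.window)
    return derived, report, traces_z


_MEASURE_COLUMNS = (
    ["mean_size_" + c for c in CONDITIONS]
    + ["mean_dilation_" + c for c in CONDITIONS]
    + ["diff_reward_minus_neutral", "diff_reward_minus_control",
       "median_rt_reward", "median_rt_neutral"])


def derived_to_row(ds: SubjectDataset, derived: DerivedMeasures) -> dict:
    row = {"subject_id": ds.subject_id, "group": ds.clinical.group}
    for c in CONDITIONS:
        row["mean_size_" + c] = derived.mean_size[c]
        row["mean_dilation_" + c] = derived.mean_dilation[c]
        row["n_kept_" + c] = derived.n_kept[c]
    row["diff_reward_minus_neutral"] = derived.diff_reward_minus_neutral
    row["diff_reward_minus_control"] = derived.diff_reward_minus_control
    row["median_rt_reward"] = derived.median_rt["reward"]
    row["median_rt_neutral"] = derived.median_rt["neutral"]
    return row


def preprocess_cohort(datasets: list,
                      params: PreprocessParams = PreprocessParams()) -> tuple:
    """Preprocess every subject; returns ``(derived_df, qc_df, processed)``.

    ``derived_df`` has one row per subject that survived run-level QC,
    ``qc_df`` one row per subject-run plus one per discarded trial, and
    ``processed`` maps subject_id -> z-scored kept traces (for reliability
    analyses).
    """
    derived_rows, qc_rows, processed = [], [], {}
    for ds in datasets:
        derived, report, traces_z = preprocess_subject(ds, params)
        qc_rows.append({
            "subject_id": ds.subject_id, "level": "run",
            "run_missing_fraction": report.run_missing_fraction,
            "run_excluded": report.run_excluded,
            "discarded_fraction": report.discarded_fraction,
            "detail": ""})
        for cond, idx, status, reason in report.trial_status:
            if status != KEPT:
                qc_rows.append({
                    "subject_id": ds.subject_id, "level": "trial",
                    "run_missing_fraction": np.nan, "run_excluded": False,
                    "discarded_fraction": np.nan,
                    "detail": f"{cond}#{idx}: {status} ({reason})"})
        if derived is None:
            continue
        processed[ds.subject_id] = traces_z
        derived_rows.append(derived_to_row(ds, derived))
    derived_df = pd.DataFrame(derived_rows)
    qc_df = pd.DataFrame(qc_rows)
    return derived_df, qc_df, processed


def trial_score_matrix(processed: dict, datasets: list, condition: str,
                       window: tuple = (0.0, 6.0)) -> pd.DataFrame:
    """Subject x trial matrix of window-mean dilation scores for one condition.

    Discarded trials are NaN; used for split-half reliability.
    """
    by_id = {ds.subject_id: ds for ds in datasets}
    n_trials = max((t.trial_index for traces in processed.values()
                    for t in traces if t.condition == condition), default=0)
    rows = {}
    for sid, traces in processed.items():
        kept = {t.trial_index: t for t in traces if t.condition == condition}
        n_total = max([n_trials] + [r.trial_index for r in by_id[sid].trials
                                    if r.condition == condition])
        row = np.full(n_total, np.nan)
        for idx, t in kept.items():
            row[idx - 1] = window_mean_dilation(t, window)
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"trial_{i + 1}" for i in range(df.shape[1])]
    df.index.name = "subject_id"
    return df


def write_tables(derived_df: pd.DataFrame, qc_df: pd.DataFrame, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    derived_df.to_csv(out_dir / "derived_measures.csv", index=False,
                      float_format="%.12g")
    qc_df.to_csv(out_dir / "qc_report.csv", index=False, float_format="%.12g")
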