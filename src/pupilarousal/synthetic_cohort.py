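"""Synthetic cohort generator for a cued reward-anticipation pupillometry task.

The task emulated here presents three isoluminant cues for a 6 s anticipation
window each: a potentially rewarding response cue, a neutral response cue and a
no-response control cue.  Pupil size rises roughly linearly while a response is
prepared (strongest for reward, weaker for neutral) and falls during the
control cue.  An adaptive response deadline keeps reward-trial success near
50%.  Each subject also carries interview-style clinical scores (depressive
symptom count, symptom impact, anhedonia, age, sex, group), linked to the
pupillometric ground truth so that the population correlation between measured
reward dilation and symptom count matches a configurable target.

Everything is deterministic given ``CohortConfig.seed``.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, signal, stats

from .datatypes import (CONDITIONS, ClinicalScores, ConfigError, PupilTrace,
                        SubjectDataset, TrialRecord)

log = logging.getLogger(__name__)

# Fraction of the depressed group reporting >= 5 current symptoms; the
# depressed symptom-count marginal (binomial on 0..9) is solved to match it.
ACUTE_FRACTION = 23.0 / 41.0
# Control symptom-count marginal on 0..3 (controls never exceed 3 symptoms).
CONTROL_COUNT_PROBS = np.array([0.45, 0.30, 0.15, 0.10])
# Gaze excursion episodes last Uniform(min, max) seconds.
EXCURSION_DURATION_S = (0.6, 1.6)
# Displacement (screen px) applied to gaze during an excursion episode.
EXCURSION_OFFSET_PX = 400.0
# Nominal screen center and per-subject fixation-center scatter (px).
SCREEN_CENTER = (960.0, 540.0)
CENTER_SCATTER_PX = 30.0
GAZE_JITTER_PX = 15.0
# Run-level QC failures are produced by inflating the blink rate this much.
BAD_RUN_BLINK_FACTOR = 5.0
# Adaptive deadline staircase.
DEADLINE_INITIAL_S = 0.4
DEADLINE_STEP_S = 0.02
NEUTRAL_DEADLINE_S = 0.6
# Female fraction per group (matches a typical depression-study cohort).
FEMALE_FRACTION = {"control": 12 / 25, "depressed": 27 / 41}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Durations are seconds, ``sampling_rate`` Hz, ``blink_rate`` events/minute,
    slopes arbitrary pupil units per second.  Correlation targets refer to the
    *measured* per-subject scores after the documented preprocessing, i.e. the
    generator compensates analytically for trial-noise attenuation.
    """

    n_control: int = 25
    n_depressed: int = 41
    trials_per_condition: int = 10
    sampling_rate: float = 250.0
    anticipation_duration: float = 6.0
    baseline_duration: float = 1.0
    target_corr_dilation_symptoms: float = -0.5
    target_corr_dilation_rt: float = -0.5
    blink_rate: float = 15.0
    blink_duration_mean: float = 0.2
    gaze_excursion_prob: float = 0.05
    missing_run_prob: float = 0.075
    seed: int = 0
    # Signal model: population mean dilation slope per condition and the
    # between-subject SD of the reward slope (the arousal trait loading).
    slope_reward: float = 0.12
    slope_neutral: float = 0.07
    slope_control: float = -0.07
    slope_between_sd: float = 0.055
    neutral_loading: float = 0.6  # trait loading relative to reward
    control_loading: float = 0.2
    # AR(1) measurement noise added to the pupil signal.
    noise_sd: float = 0.3
    noise_ar1: float = 0.995
    # Response times (seconds): subject-level center and trial scatter.
    rt_base: float = 0.28
    rt_between_sd: float = 0.05
    rt_trial_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_depressed < 1:
            raise ConfigError("group sizes must be >= 1")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        for name in ("sampling_rate", "anticipation_duration",
                     "baseline_duration", "blink_duration_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("target_corr_dilation_symptoms", "target_corr_dilation_rt"):
            if not -1 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must lie strictly inside (-1, 1)")
        for name in ("gaze_excursion_prob", "missing_run_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.blink_rate < 0:
            raise ConfigError("blink_rate must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_depressed

    @property
    def samples_per_trial(self) -> int:
        dur = self.baseline_duration + self.anticipation_duration
        return int(round(dur * self.sampling_rate)) + 1

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        section = raw.get("cohort", raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**section)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"cohort": dataclasses.asdict(self)}, fh,
                           sort_keys=False)


@dataclass
class GroundTruth:
    """Latent generating quantities, kept for recovery tests."""

    trait: np.ndarray  # per-subject latent arousal trait, N(0, 1)
    slopes: np.ndarray  # (n_subjects, 3) noiseless dilation slope per condition
    rt_center: np.ndarray  # per-subject central response time (s)
    corr_matrix: np.ndarray  # generating correlations among (trait, symptoms, RT)
    calibration: dict = field(default_factory=dict)
    artifact_masks: dict = field(default_factory=dict)  # subject_id -> list[bool arrays]


# ---------------------------------------------------------------------------
# Symptom-count marginals and calibration
# ---------------------------------------------------------------------------

def _depressed_count_probs() -> np.ndarray:
    """Binomial(9, p) marginal with P(count >= 5) equal to the acute fraction."""
    def excess(p):
        return stats.binom.sf(4, 9, p) - ACUTE_FRACTION
    p = optimize.brentq(excess, 0.05, 0.95)
    return stats.binom.pmf(np.arange(10), 9, p)


_DEP_COUNT_PROBS = _depressed_count_probs()


def _pooled_count_moments(config: CohortConfig) -> tuple:
    """Mean and SD of symptom count over the configured group mixture."""
    w_c = config.n_control / config.n_subjects
    w_d = 1.0 - w_c
    k_c = np.arange(4)
    k_d = np.arange(10)
    m_c = float(CONTROL_COUNT_PROBS @ k_c)
    m_d = float(_DEP_COUNT_PROBS @ k_d)
    ex2 = w_c * float(CONTROL_COUNT_PROBS @ k_c**2) + w_d * float(_DEP_COUNT_PROBS @ k_d**2)
    mean = w_c * m_c + w_d * m_d
    var = ex2 - mean**2
    return mean, math.sqrt(var)


def dilation_noise_variance(config: CohortConfig) -> float:
    """Variance of the trial-level noise on the window-mean dilation score.

    The window-mean of the first derivative telescopes to
    (x(T) - x(0)) / T, so only the AR(1) noise at the two window endpoints
    contributes: var = 2 sigma^2 (1 - phi^(T f)) / T^2.
    """
    T = config.anticipation_duration
    lag = int(round(T * config.sampling_rate))
    rho_lag = config.noise_ar1 ** lag
    return 2.0 * config.noise_sd**2 * (1.0 - rho_lag) / T**2


def _expected_gaze_discard_prob(config: CohortConfig, max_outside: float = 1.0) -> float:
    lo, hi = EXCURSION_DURATION_S
    p_long = float(np.clip((hi - max_outside) / (hi - lo), 0.0, 1.0))
    return config.gaze_excursion_prob * p_long


_CALIBRATION_SEED = 746293541
_CALIBRATION_SUBJECTS = 800
_ATTENUATION_KEYS = (
    "trials_per_condition", "sampling_rate", "anticipation_duration",
    "baseline_duration", "blink_rate", "blink_duration_mean",
    "gaze_excursion_prob", "slope_reward", "slope_neutral", "slope_control",
    "slope_between_sd", "neutral_loading", "control_loading", "noise_sd",
    "noise_ar1")
_attenuation_cache: dict = {}


def measurement_attenuation(config: CohortConfig) -> float:
    """Attenuation of corr(measured reward dilation, true slope).

    The measured score is attenuated by trial-level AR(1) noise at the
    averaging-window endpoints *and* by the sampling noise of the per-run
    z-scoring divisor, plus QC trial losses.  A closed form for the combined
    effect is impractical, so the generator measures it once per
    noise-parameter configuration: a fixed-seed internal simulation pushes
    subjects with stratified latent traits through the full default
    preprocessing pipeline and correlates measured scores with the
    generating slopes.  The result is cached, deterministic, and independent
    of cohort size, seed and correlation targets.
    """
    key = tuple(getattr(config, k) for k in _ATTENUATION_KEYS)
    if key in _attenuation_cache:
        return _attenuation_cache[key]
    from .preprocess import preprocess_subject  # deferred: avoids cycle at import

    n_cal = _CALIBRATION_SUBJECTS
    cal_cfg = dataclasses.replace(
        config, n_control=n_cal, n_depressed=1, missing_run_prob=0.0,
        target_corr_dilation_symptoms=0.0, target_corr_dilation_rt=0.0,
        seed=_CALIBRATION_SEED)
    # Stratified standard-normal traits: removes trait-sampling noise from
    # the attenuation estimate.
    trait = stats.norm.ppf((np.arange(n_cal) + 0.5) / n_cal)
    lat = {
        "groups": ["control"] * n_cal,
        "counts": np.zeros(n_cal, dtype=int),
        "trait": trait,
        "z_rt": np.zeros(n_cal),
        "slopes": np.column_stack([
            config.slope_reward + config.slope_between_sd * trait,
            config.slope_neutral + config.neutral_loading * config.slope_between_sd * trait,
            config.slope_control + config.control_loading * config.slope_between_sd * trait]),
        "rt_center": np.full(n_cal, config.rt_base),
        "impact": np.zeros(n_cal, dtype=int),
        "anhedonia": np.zeros(n_cal),
        "age": np.full(n_cal, 30.0),
        "cal": None,
    }
    rng = np.random.default_rng(_CALIBRATION_SEED)
    meas, slope = [], []
    for i in range(n_cal):
        ds, _ = _build_subject(i, lat, cal_cfg, rng)
        derived, _, _ = preprocess_subject(ds)
        if derived is None or not np.isfinite(derived.mean_dilation["reward"]):
            continue
        meas.append(derived.mean_dilation["reward"])
        slope.append(lat["slopes"][i, 0])
    a = float(np.corrcoef(meas, slope)[0, 1])
    _attenuation_cache[key] = a
    return a


_median_var_cache: dict = {}


def _normal_median_variance(m: int) -> float:
    """Variance of the median of m standard normals (finite-m, not pi/2m).

    Computed once per m from a large fixed-seed draw; for m = 10 this is
    ~0.138 versus the asymptotic pi/(2*10) = 0.157.
    """
    if m not in _median_var_cache:
        if m == 1:
            _median_var_cache[m] = 1.0
        else:
            rng = np.random.default_rng(97531)
            _median_var_cache[m] = float(
                np.median(rng.standard_normal((200000, m)), axis=1).var())
    return _median_var_cache[m]


def calibrate(config: CohortConfig) -> dict:
    """Work out the latent loadings that hit the configured correlation targets.

    Measured reward dilation behaves as an attenuated reading of the true
    slope, corr(measured, X) = a_dil * corr(slope, X); the latent loadings
    are the targets divided by the attenuation factors (a_dil from
    :func:`measurement_attenuation`, the RT-median factor in closed form).
    Raises :class:`ConfigError` when a target is infeasible (|loading| >= 1).
    """
    m = config.trials_per_condition
    need_dilation = (config.target_corr_dilation_symptoms != 0
                     or config.target_corr_dilation_rt != 0)
    if need_dilation and config.noise_sd > 0:
        a_dil = measurement_attenuation(config)
    else:
        a_dil = 1.0
    v_med = _normal_median_variance(m) * config.rt_trial_sd**2
    a_rt = math.sqrt(config.rt_between_sd**2 / (config.rt_between_sd**2 + v_med))
    c_sym = config.target_corr_dilation_symptoms / a_dil
    c_rt = config.target_corr_dilation_rt / (a_dil * a_rt)
    corr = np.array([
        [1.0, c_sym, c_rt],
        [c_sym, 1.0, c_sym * c_rt],
        [c_rt, c_sym * c_rt, 1.0],
    ])
    if abs(c_sym) >= 1 or abs(c_rt) >= 1 or np.linalg.eigvalsh(corr).min() < -1e-12:
        raise ConfigError(
            "infeasible correlation targets: the implied latent correlation "
            f"matrix (loadings {c_sym:.3f}, {c_rt:.3f}) is not positive "
            "semi-definite")
    return {"a_dil": a_dil, "a_rt": a_rt, "c_sym": c_sym, "c_rt": c_rt,
            "corr_matrix": corr}


# ---------------------------------------------------------------------------
# Trace-level generation
# ---------------------------------------------------------------------------

def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    white = rng.standard_normal(shape)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    x0 = rng.standard_normal(shape[:-1] + (1,)) * sd
    zi = (phi * x0)[..., :1]
    out, _ = signal.lfilter([innov_sd], [1.0, -phi], white, axis=-1, zi=zi)
    return out


def generate_subject_traces(slopes: dict, conditions: list, config: CohortConfig,
                            rng: np.random.Generator,
                            noise_sd: float = None) -> list:
    """Noisy (but artifact-free) traces for one subject-run.

    ``slopes`` maps condition -> noiseless dilation slope (units/s);
    ``conditions`` is the run's trial sequence.  The pupil signal is flat at 0
    during the baseline and ramps linearly (slope * t) during anticipation;
    stationary AR(1) noise is added on top.  ``noise_sd`` overrides the
    configured noise amplitude (0 gives noiseless traces).
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    n = config.samples_per_trial
    t = np.arange(n) / config.sampling_rate - config.baseline_duration
    ramp = np.where(t >= 0, t, 0.0)
    n_trials = len(conditions)
    if noise_sd > 0:
        noise = _ar1_noise(rng, (n_trials, n), noise_sd, config.noise_ar1)
    else:
        noise = np.zeros((n_trials, n))
    cx = SCREEN_CENTER[0] + rng.normal(0, CENTER_SCATTER_PX)
    cy = SCREEN_CENTER[1] + rng.normal(0, CENTER_SCATTER_PX)
    gaze_x = cx + rng.normal(0, GAZE_JITTER_PX, (n_trials, n))
    gaze_y = cy + rng.normal(0, GAZE_JITTER_PX, (n_trials, n))
    counters = {c: 0 for c in CONDITIONS}
    traces = []
    for i, cond in enumerate(conditions):
        counters[cond] += 1
        traces.append(PupilTrace(
            time=t.copy(),
            pupil=slopes[cond] * ramp + noise[i],
            gaze_x=gaze_x[i], gaze_y=gaze_y[i],
            valid=np.ones(n, dtype=bool),
            condition=cond, trial_index=counters[cond]))
    return traces


def inject_artifacts(trace: PupilTrace, config: CohortConfig,
                     rng: np.random.Generator,
                     blink_rate: float = None, copy: bool = True) -> tuple:
    """Add blink missingness and gaze excursions to a clean trace.

    Blinks arrive as a Poisson process (``blink_rate`` events/minute, duration
    truncated-normal around ``blink_duration_mean``) and blank the pupil
    samples; a gaze excursion (probability ``gaze_excursion_prob`` per trial)
    displaces the gaze coordinates for one contiguous episode.  Returns
    ``(trace, mask)`` where ``mask`` flags every altered sample.
    """
    if blink_rate is None:
        blink_rate = config.blink_rate
    if copy:
        trace = trace.copy()
    n = len(trace.time)
    rate = config.sampling_rate
    duration_s = n / rate
    mask = np.zeros(n, dtype=bool)

    n_blinks = rng.poisson(blink_rate * duration_s / 60.0)
    for _ in range(n_blinks):
        dur = max(rng.normal(config.blink_duration_mean,
                             0.3 * config.blink_duration_mean), 0.02)
        k = int(round(dur * rate))
        start = rng.integers(0, max(n - k, 1))
        mask[start:start + k] = True
    trace.pupil[mask] = np.nan
    trace.valid[mask] = False

    if rng.random() < config.gaze_excursion_prob:
        dur = rng.uniform(*EXCURSION_DURATION_S)
        k = min(int(round(dur * rate)), n)
        start = rng.integers(0, max(n - k, 1))
        sgn = 1.0 if rng.random() < 0.5 else -1.0
        trace.gaze_x[start:start + k] += sgn * EXCURSION_OFFSET_PX
        mask[start:start + k] = True
    return trace, mask


def simulate_adaptive_deadline(rts: np.ndarray,
                               initial: float = DEADLINE_INITIAL_S,
                               step: float = DEADLINE_STEP_S) -> tuple:
    """Fixed-step staircase on the response deadline.

    The deadline shortens after a success (rt < deadline) and lengthens after
    a failure, so the long-run success proportion converges to 0.5.  Returns
    ``(success_flags, deadline_trajectory)``; the trajectory holds the deadline
    in force on each trial.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 1:
        raise ValueError("need at least one response time")
    deadlines = np.empty(rts.size)
    success = np.empty(rts.size, dtype=bool)
    d = float(initial)
    for i, rt in enumerate(rts):
        deadlines[i] = d
        success[i] = rt < d
        d += -step if success[i] else step
    return success, deadlines


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

def _draw_cohort_latents(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Subject-level latent variables and clinical scores for the whole cohort."""
    cal = calibrate(config)
    n = config.n_subjects
    groups = ["control"] * config.n_control + ["depressed"] * config.n_depressed

    counts = np.empty(n, dtype=int)
    for i, g in enumerate(groups):
        probs = CONTROL_COUNT_PROBS if g == "control" else _DEP_COUNT_PROBS
        counts[i] = rng.choice(len(probs), p=probs)
    mean_c, sd_c = _pooled_count_moments(config)
    z_count = (counts - mean_c) / sd_c

    c_sym, c_rt = cal["c_sym"], cal["c_rt"]
    trait = c_sym * z_count + math.sqrt(1 - c_sym**2) * rng.standard_normal(n)
    z_rt = c_rt * trait + math.sqrt(1 - c_rt**2) * rng.standard_normal(n)

    slopes = np.column_stack([
        config.slope_reward + config.slope_between_sd * trait,
        config.slope_neutral + config.neutral_loading * config.slope_between_sd * trait,
        config.slope_control + config.control_loading * config.slope_between_sd * trait,
    ])
    rt_center = config.rt_base + config.rt_between_sd * z_rt

    impact = np.clip(np.round(counts + rng.normal(0, 1.2, n)), 0, 10).astype(int)
    anhedonia = np.round(np.clip(0.30 * counts + rng.normal(0, 0.5, n), 0, None), 3)
    age = np.clip(np.round(rng.normal(34, 12, n), 1), 18, 65)
    return {"groups": groups, "counts": counts, "trait": trait, "z_rt": z_rt,
            "slopes": slopes, "rt_center": rt_center, "impact": impact,
            "anhedonia": anhedonia, "age": age, "cal": cal}


def _build_subject(i: int, lat: dict, config: CohortConfig,
                   rng: np.random.Generator) -> tuple:
    """One subject's traces, trials and clinical scores; returns (dataset, masks)."""
    g = lat["groups"][i]
    width = len(str(config.n_subjects))
    sid = f"sub-{i + 1:0{width}d}"
    female = rng.random() < FEMALE_FRACTION[g]
    clinical = ClinicalScores(
        symptom_count=int(lat["counts"][i]),
        symptom_impact=int(lat["impact"][i]),
        anhedonia=float(lat["anhedonia"][i]), age=float(lat["age"][i]),
        sex="f" if female else "m", group=g)
    conditions = list(rng.permutation(
        np.repeat(CONDITIONS, config.trials_per_condition)))
    subj_slopes = dict(zip(CONDITIONS, lat["slopes"][i]))
    traces = generate_subject_traces(subj_slopes, conditions, config, rng)
    bad_run = rng.random() < config.missing_run_prob
    blink_rate = config.blink_rate * (BAD_RUN_BLINK_FACTOR if bad_run else 1.0)
    masks = []
    for tr in traces:
        _, m = inject_artifacts(tr, config, rng, blink_rate=blink_rate,
                                copy=False)
        masks.append(m)

    reward_idx = [j for j, c in enumerate(conditions) if c == "reward"]
    neutral_idx = [j for j, c in enumerate(conditions) if c == "neutral"]
    rts = np.full(len(conditions), np.nan)
    rts[reward_idx + neutral_idx] = np.clip(
        lat["rt_center"][i] + rng.normal(0, config.rt_trial_sd,
                                         len(reward_idx) + len(neutral_idx)),
        0.1, None)
    success = np.full(len(conditions), None, dtype=object)
    if reward_idx:
        flags, _ = simulate_adaptive_deadline(rts[reward_idx])
        for j, f in zip(reward_idx, flags):
            success[j] = bool(f)
    for j in neutral_idx:
        success[j] = bool(rts[j] < NEUTRAL_DEADLINE_S)

    trials = [TrialRecord(condition=c, trial_index=tr.trial_index,
                          rt=float(rts[j]), success=success[j])
              for j, (c, tr) in enumerate(zip(conditions, traces))]
    return SubjectDataset(subject_id=sid, clinical=clinical,
                          traces=traces, trials=trials), masks


def generate_cohort(config: CohortConfig) -> tuple:
    """Generate a full cohort: ``(list[SubjectDataset], GroundTruth)``.

    Identical config (including seed) yields identical output.  For cohorts
    of thousands of subjects prefer :func:`iter_cohort`, which yields one
    subject at a time instead of holding every trace in memory.
    """
    rng = np.random.default_rng(config.seed)
    lat = _draw_cohort_latents(config, rng)
    datasets, masks = [], {}
    for i in range(config.n_subjects):
        ds, m = _build_subject(i, lat, config, rng)
        datasets.append(ds)
        masks[ds.subject_id] = m
    gt = GroundTruth(trait=lat["trait"], slopes=lat["slopes"],
                     rt_center=lat["rt_center"],
                     corr_matrix=lat["cal"]["corr_matrix"],
                     calibration={k: v for k, v in lat["cal"].items()
                                  if k != "corr_matrix"},
                     artifact_masks=masks)
    return datasets, gt


def iter_cohort(config: CohortConfig):
    """Yield ``(SubjectDataset, masks)`` one subject at a time.

    Produces byte-identical subjects to :func:`generate_cohort` (same rng
    consumption order) without retaining the whole cohort.
    """
    rng = np.random.default_rng(config.seed)
    lat = _draw_cohort_latents(config, rng)
    for i in range(config.n_subjects):
        yield _build_subject(i, lat, config, rng)


# ---------------------------------------------------------------------------
# File interface
# ---------------------------------------------------------------------------

FLOAT_FMT = "%.12g"


def write_cohort(datasets: list, out_dir) -> None:
    """Write trace files, trial table, clinical table and manifest.

    One delimited trace file per subject-run (columns time_s, pupil, gaze_x,
    gaze_y, valid; run-continuous time), a cohort-level ``trials.csv`` with
    per-trial condition/onset/RT/success, ``clinical.csv`` with one row per
    subject and ``manifest.csv`` mapping subjects to trace files.
    """
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    manifest, clinical_rows, trial_rows = [], [], []
    for ds in datasets:
        rel = f"traces/{ds.subject_id}.csv"
        parts = []
        start = 0.0
        trial_dur = None
        for tr, rec in zip(ds.traces, ds.trials):
            base = -tr.time[0]
            trial_dur = tr.time[-1] + base + 1.0 / tr.sampling_rate
            cue_onset = start + base
            parts.append(pd.DataFrame({
                "time_s": tr.time + cue_onset,
                "pupil": tr.pupil,
                "gaze_x": tr.gaze_x, "gaze_y": tr.gaze_y,
                "valid": tr.valid.astype(int)}))
            trial_rows.append({
                "subject_id": ds.subject_id, "condition": rec.condition,
                "trial_index": rec.trial_index, "onset_s": cue_onset,
                "rt": rec.rt, "success": "" if rec.success is None else int(rec.success)})
            start += trial_dur
        pd.concat(parts, ignore_index=True).to_csv(
            out_dir / rel, index=False, float_format=FLOAT_FMT)
        c = ds.clinical
        clinical_rows.append({
            "subject_id": ds.subject_id, "group": c.group,
            "symptom_count": c.symptom_count, "symptom_impact": c.symptom_impact,
            "anhedonia": c.anhedonia, "age": c.age, "sex": c.sex,
            "acute_flag": int(c.acute_flag)})
        manifest.append({"subject_id": ds.subject_id, "group": c.group,
                         "trace_file": rel, "n_trials": len(ds.trials),
                         "trial_duration_s": trial_dur})
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False,
                                  float_format=FLOAT_FMT)
    pd.DataFrame(clinical_rows).to_csv(out_dir / "clinical.csv", index=False,
                                       float_format=FLOAT_FMT)
    pd.DataFrame(trial_rows).to_csv(out_dir / "trials.csv", index=False,
                                    float_format=FLOAT_FMT)


def read_cohort(in_dir) -> list:
    """Re-assemble :class:`SubjectDataset` objects written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    clinical = pd.read_csv(in_dir / "clinical.csv").set_index("subject_id")
    trials = pd.read_csv(in_dir / "trials.csv")
    datasets = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        df = pd.read_csv(in_dir / row["trace_file"])
        sub_trials = trials[trials["subject_id"] == sid]
        n_per = len(df) // len(sub_trials)
        traces, recs = [], []
        for k, (_, trow) in enumerate(sub_trials.iterrows()):
            seg = df.iloc[k * n_per:(k + 1) * n_per]
            t = seg["time_s"].to_numpy() - trow["onset_s"]  # cue-relative
            valid = seg["valid"].to_numpy().astype(bool)
            traces.append(PupilTrace(
                time=t,
                pupil=seg["pupil"].to_numpy(),
                gaze_x=seg["gaze_x"].to_numpy(), gaze_y=seg["gaze_y"].to_numpy(),
                valid=valid, condition=trow["condition"],
                trial_index=int(trow["trial_index"])))
            success = trow["success"]
            recs.append(TrialRecord(
                condition=trow["condition"], trial_index=int(trow["trial_index"]),
                rt=float(trow["rt"]),
                success=None if pd.isna(success) else bool(int(success))))
        crow = clinical.loc[sid]
        datasets.append(SubjectDataset(
            subject_id=sid,
            clinical=ClinicalScores(
                symptom_count=int(crow["symptom_count"]),
                symptom_impact=int(crow["symptom_impact"]),
                anhedonia=float(crow["anhedonia"]), age=float(crow["age"]),
                sex=str(crow["sex"]), group=str(crow["group"])),
            traces=traces, trials=recs))
    return datasets
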