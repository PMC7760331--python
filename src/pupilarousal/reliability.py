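"""Split-half reliability of per-trial scores, feeding SEMs downstream.

The default scheme correlates each subject's mean over the first half of
trials (1-5 with 10 trials per condition) with the mean over the second half
(6-10), across subjects.  An odd/even split is available because slow drift
can bias a first/last split.  The Spearman-Brown step-up 2r/(1+r) is reported
alongside the raw correlation but never silently substituted — the raw split
correlation is the headline value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .latent import sem_from_reliability

log = logging.getLogger(__name__)

SPLIT_FIRST_LAST = "split_half_first_last"
SPLIT_ODD_EVEN = "split_half_odd_even"
TEST_RETEST = "test_retest"


@dataclass
class ReliabilityEstimate:
    method: str
    r: float
    n_subjects: int
    adjusted: bool = False
    r_adjusted: float = np.nan  # Spearman-Brown step-up, split-half only
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("reliability correlation must lie in [-1, 1]")


def spearman_brown(r: float) -> float:
    """Step-up correction for doubling the test length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(scores, scheme: str = SPLIT_FIRST_LAST) -> ReliabilityEstimate:
    """Split-half reliability of a subjects x trials score matrix.

    NaN entries are discarded trials; a subject with an empty half is dropped
    (and logged).  Requires >= 4 contributing subjects and >= 2 trials per
    half in the design.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a subjects x trials matrix")
    n_trials = scores.shape[1]
    if n_trials < 4:
        raise ValueError("need at least 2 trials per half")
    if scheme == SPLIT_FIRST_LAST:
        first = scores[:, : n_trials // 2]
        second = scores[:, n_trials // 2:]
    elif scheme == SPLIT_ODD_EVEN:
        first = scores[:, 0::2]
        second = scores[:, 1::2]
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN halves
        m1 = np.nanmean(first, axis=1)
        m2 = np.nanmean(second, axis=1)
    ok = np.isfinite(m1) & np.isfinite(m2)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("split-half: dropped %d subject(s) with an empty half",
                 n_dropped)
    if ok.sum() < 4:
        raise ValueError("need at least 4 subjects with both halves")
    r = float(np.corrcoef(m1[ok], m2[ok])[0, 1])
    return ReliabilityEstimate(method=scheme, r=r, n_subjects=int(ok.sum()),
                               adjusted=False, r_adjusted=spearman_brown(r),
                               n_dropped=n_dropped)


def reliability_to_sem(estimate: ReliabilityEstimate, sd: float) -> float:
    """SEM from a reliability estimate: SD * sqrt(1 - r).

    Negative reliabilities are rejected — they indicate that the score
    carries no stable between-subject signal, and the SEM formula would not
    be meaningful; collect more trials or use a different score.
    """
    if estimate.r < 0:
        raise ValueError(
            "negative reliability: the split-half correlation must be >= 0 "
            "for a meaningful SEM (the measure shows no stable "
            "between-subject variance)")
    return sem_from_reliability(sd, estimate.r)


def reliability_table(estimates: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": e.method, "r": e.r, "r_adjusted": e.r_adjusted,
        "n_subjects": e.n_subjects, "n_dropped": e.n_dropped}
        for e in estimates])


def write_reliability(estimates: list, path) -> None:
    reliability_table(estimates).to_csv(path, index=False, float_format="%.6g")
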