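"""Default Bayes factors for correlations and two-sample t-tests.

The correlation test follows the standard default Bayesian correlation
analysis: the population correlation rho carries a stretched beta prior of
width w — a Beta(1/w, 1/w) distribution linearly mapped onto (-1, 1); width 1
is the uniform prior — and the Bayes factor is

    BF10 = integral pi(rho) p(r | rho, n) drho / p(r | 0, n),

with p(r | rho, n) the *exact* sampling density of the Pearson correlation of
n bivariate-normal pairs (no Fisher-z approximation), so the analysis is a
function of the sufficient statistics (n, r) alone.

The two-sample test is the default JZS t-test: a Cauchy(0, scale) prior on
the standardized effect size, with BF10 the ratio of the marginal likelihood
of the observed t statistic (noncentral t after integrating the effect prior)
to the central-t null likelihood.

Both integrals are evaluated by adaptive quadrature; Monte Carlo
prior-sampling estimators are provided as independent cross-checks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, special, stats

TWO_SIDED = "two_sided"
NEGATIVE = "negative"
POSITIVE = "positive"
_SIDES = (TWO_SIDED, NEGATIVE, POSITIVE)


@dataclass(frozen=True)
class CorrelationPrior:
    """Stretched beta prior on a correlation; width 1 is uniform on (-1, 1)."""

    width: float = 1.0
    sidedness: str = TWO_SIDED

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("prior width must be > 0")
        if self.sidedness not in _SIDES:
            raise ValueError(f"sidedness must be one of {_SIDES}")

    @property
    def alpha(self) -> float:
        return 1.0 / self.width

    def pdf(self, rho) -> np.ndarray:
        """Density on (-1, 1), renormalized on the half-line for one-sided use."""
        rho = np.asarray(rho, dtype=float)
        base = stats.beta.pdf((rho + 1.0) / 2.0, self.alpha, self.alpha) / 2.0
        if self.sidedness == NEGATIVE:
            return np.where(rho < 0, 2.0 * base, 0.0)
        if self.sidedness == POSITIVE:
            return np.where(rho > 0, 2.0 * base, 0.0)
        return base

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        u = stats.beta.rvs(self.alpha, self.alpha, size=size, random_state=rng)
        rho = 2.0 * u - 1.0
        if self.sidedness == NEGATIVE:
            return -np.abs(rho)
        if self.sidedness == POSITIVE:
            return np.abs(rho)
        return rho


@dataclass
class EvidenceResult:
    """A Bayes-factor outcome with its prior specification."""

    statistic: float  # r or t
    n: int  # total n (n1 + n2 for the t-test)
    bf10: float
    prior: str
    sidedness: str = TWO_SIDED
    n2: Optional[int] = None

    @property
    def log10_bf10(self) -> float:
        return float(np.log10(self.bf10))

    @property
    def band(self) -> str:
        return classify_evidence(self.bf10)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Sample Pearson correlation with explicit input validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() < 1e-14 or y.std() < 1e-14:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def log_r_sampling_density(r, rho, n: int):
    """Log of the exact density of the sample correlation r given rho and n.

    Closed form for n >= 4 bivariate-normal pairs, expressed through the
    Gauss hypergeometric function; vectorized over r and/or rho.
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if n < 4:
        raise ValueError("n must be >= 4")
    if np.any(np.abs(r) >= 1) or np.any(np.abs(rho) >= 1):
        raise ValueError("|r| and |rho| must be < 1")
    return (np.log(n - 2) + special.gammaln(n - 1) - 0.5 * np.log(2 * np.pi)
            - special.gammaln(n - 0.5)
            + ((n - 1) / 2.0) * np.log1p(-rho**2)
            + ((n - 4) / 2.0) * np.log1p(-r**2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)))


def r_sampling_density(r, rho, n: int):
    """Exact sampling density of the Pearson correlation (see log version)."""
    return np.exp(log_r_sampling_density(r, rho, n))


def correlation_bf(n: int, r: float,
                   prior: CorrelationPrior = CorrelationPrior()) -> EvidenceResult:
    """Bayes factor BF10 for a Pearson correlation from sufficient statistics.

    Computed by adaptive quadrature of the exact r sampling density against
    the stretched beta prior; deterministic given (n, r, prior).
    """
    if not -1 < r < 1:
        raise ValueError("|r| must be < 1")
    log_null = log_r_sampling_density(r, 0.0, n)

    def integrand(rho):
        return prior.pdf(rho) * np.exp(log_r_sampling_density(r, rho, n) - log_null)

    if prior.sidedness == NEGATIVE:
        lo, hi = -1.0, 0.0
    elif prior.sidedness == POSITIVE:
        lo, hi = 0.0, 1.0
    else:
        lo, hi = -1.0, 1.0
    bf, err = integrate.quad(integrand, lo, hi, limit=200, epsabs=0.0,
                             epsrel=1e-9)
    if not np.isfinite(bf) or (bf > 0 and err / bf > 1e-6):
        raise RuntimeError(
            f"correlation BF quadrature did not converge (value {bf}, "
            f"error estimate {err})")
    return EvidenceResult(statistic=float(r), n=int(n), bf10=float(bf),
                          prior=f"stretched beta width {prior.width:g}",
                          sidedness=prior.sidedness)


def correlation_bf_from_data(x, y,
                             prior: CorrelationPrior = CorrelationPrior()) -> EvidenceResult:
    """Vector interface: compute r from the data, then the sufficient-statistic BF."""
    x = np.asarray(x, dtype=float)
    return correlation_bf(x.size, pearson_r(x, y), prior)


def mc_correlation_bf(n: int, r: float, prior: CorrelationPrior = CorrelationPrior(),
                      draws: int = 10**6, seed: int = 0) -> tuple:
    """Monte Carlo cross-check of :func:`correlation_bf`.

    Averages the likelihood ratio over prior draws of rho; returns
    ``(estimate, mc_standard_error)``.
    """
    rng = np.random.default_rng(seed)
    rho = prior.rvs(draws, rng)
    w = np.exp(log_r_sampling_density(r, rho, n)
               - log_r_sampling_density(r, 0.0, n))
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(draws))


# ---------------------------------------------------------------------------
# JZS two-sample t-test
# ---------------------------------------------------------------------------

def t_from_summaries(n1: int, mean1: float, sd1: float,
                     n2: int, mean2: float, sd2: float) -> float:
    """Pooled-variance two-sample t statistic."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 < 1e-24:
        raise ValueError("degenerate (zero) pooled variance")
    return (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def jzs_ttest_bf(t: float, n1: int, n2: int,
                 cauchy_scale: float = 0.7) -> EvidenceResult:
    """Default Bayesian two-sample t-test from the t statistic.

    Effect size delta ~ Cauchy(0, scale); BF10 integrates the noncentral-t
    likelihood of the observed t over that prior and divides by the central-t
    null likelihood.  The t statistic is sufficient.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be > 0")
    df = n1 + n2 - 2
    neff = np.sqrt(n1 * n2 / (n1 + n2))
    null = stats.t.pdf(t, df)

    def integrand(delta):
        return (stats.nct.pdf(t, df, delta * neff)
                * stats.cauchy.pdf(delta, 0.0, cauchy_scale))

    num, err = integrate.quad(integrand, -np.inf, np.inf, limit=400,
                              epsabs=0.0, epsrel=1e-9)
    bf = num / null
    if not np.isfinite(bf) or (num > 0 and err / num > 1e-6):
        raise RuntimeError("JZS t-test quadrature did not converge")
    return EvidenceResult(statistic=float(t), n=int(n1), n2=int(n2),
                          bf10=float(bf),
                          prior=f"Cauchy(0, {cauchy_scale:g}) on effect size")


def jzs_ttest_bf_from_data(a, b, cauchy_scale: float = 0.7) -> EvidenceResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = t_from_summaries(a.size, a.mean(), a.std(ddof=1),
                         b.size, b.mean(), b.std(ddof=1))
    return jzs_ttest_bf(t, a.size, b.size, cauchy_scale)


def mc_jzs_bf(t: float, n1: int, n2: int, cauchy_scale: float = 0.7,
              draws: int = 10**6, seed: int = 0) -> tuple:
    """Monte Carlo cross-check of :func:`jzs_ttest_bf` (prior-predictive)."""
    rng = np.random.default_rng(seed)
    df = n1 + n2 - 2
    neff = np.sqrt(n1 * n2 / (n1 + n2))
    delta = stats.cauchy.rvs(0.0, cauchy_scale, size=draws, random_state=rng)
    w = stats.nct.pdf(t, df, delta * neff) / stats.t.pdf(t, df)
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(draws))


# ---------------------------------------------------------------------------
# Partial correlation and evidence bands
# ---------------------------------------------------------------------------

def partial_correlation_bf(x, y, covariates,
                           prior: CorrelationPrior = CorrelationPrior()) -> EvidenceResult:
    """Correlation BF after least-squares residualization on covariates.

    x and y are regressed on the covariates plus an intercept; the residual
    correlation enters :func:`correlation_bf` with effective
    n = n - (number of covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    k = Z.shape[1]
    if x.size <= k + 3:
        raise ValueError("need n > number of covariates + 3")
    design = np.column_stack([np.ones(x.size), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if rx.std() < 1e-12 * max(x.std(), 1e-300) or \
            ry.std() < 1e-12 * max(y.std(), 1e-300):
        raise ValueError("zero residual variance after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return correlation_bf(x.size - k, r, prior)


_BANDS = ((3.0, "anecdotal"), (10.0, "moderate"), (30.0, "strong"),
          (100.0, "very strong"), (np.inf, "extreme"))


def classify_evidence(bf10: float) -> str:
    """Evidence band label for a BF10 (reciprocal bands favor the null).

    Bands for H1: (1, 3] anecdotal, (3, 10] moderate, (10, 30] strong,
    (30, 100] very strong, > 100 extreme; mirrored reciprocal intervals for
    H0; exactly 1 is equivocal.
    """
    if not bf10 > 0:
        raise ValueError("bf10 must be > 0")
    if bf10 == 1.0:
        return "equivocal"
    favors = "H1" if bf10 > 1 else "H0"
    mag = bf10 if bf10 > 1 else 1.0 / bf10
    for cut, name in _BANDS:
        if mag <= cut:
            return f"{name} ({favors})"
    raise AssertionError("unreachable")
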