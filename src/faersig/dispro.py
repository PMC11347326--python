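"""Disproportionality statistics for drug–event signal detection.

Each (drug, term) pair is summarized against the database background by
a 2x2 contingency table::

                    target term    other terms
    target drug          a              b
    other drugs          c              d

Four estimators are computed on every table:

* **ROR** — reporting odds ratio ``ad/bc`` with a log-normal 95% CI
  (Wald interval on the log scale).
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
  a Pearson chi-square statistic (Yates-corrected by default).
* **BCPNN IC** — the information component, a shrunken log2
  observed-to-expected ratio ``log2((a+0.5)/(E+0.5))`` with
  ``E=(a+b)(a+c)/N``, and its lower credibility bound IC025 from the
  Noren closed-form approximation.  The original beta-parameterized
  variant is available as an option.
* **MGPS EBGM** — the empirical Bayes geometric mean of the relative
  reporting rate under DuMouchel's two-component gamma mixture prior,
  with EBGM05 its 5th posterior percentile.

Signal positivity uses the conventional thresholds (each configurable):
ROR: a>=3 and CI lower bound > 1; PRR: a>=3, PRR>=2, chi2>=4;
BCPNN: IC025 > 0; MGPS: EBGM05 > 2.  A term flagged by at least one
method is a potential signal.  No multiple-testing adjustment is
applied: flags have raw-signal semantics, as is standard practice in
spontaneous-report screening.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TermLevel",
    "ContingencyTable",
    "GPSHyperparams",
    "SignalThresholds",
    "SignalResult",
    "build_contingency",
    "ror",
    "prr_chi2",
    "bcpnn_ic",
    "fit_gps_prior",
    "ebgm",
    "ebgm_from_counts",
    "flag_signals",
    "evaluate_terms",
    "events_to_soc",
    "CANONICAL_PRIOR",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class TermLevel(str, enum.Enum):
    PT = "PT"
    SOC = "SOC"


class DegenerateBackgroundError(ValueError):
    """Cohort or background margin of the 2x2 table is empty."""


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d counts for one (drug, term) pair against the background."""

    a: int
    b: int
    c: int
    d: int
    term: str = ""
    level: TermLevel = TermLevel.PT

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def build_contingency(
    cohort_events: set[tuple[str, str]],
    background_events: set[tuple[str, str]],
    term: str,
    level: TermLevel = TermLevel.PT,
) -> ContingencyTable:
    """Count the 2x2 table for ``term`` from distinct (report, term) events.

    The two event sets must be disjoint in reports.  Raises
    :class:`DegenerateBackgroundError` when either margin is empty.
    """
    a = sum(1 for _, t in cohort_events if t == term)
    b = len(cohort_events) - a
    c = sum(1 for _, t in background_events if t == term)
    d = len(background_events) - c
    if a + b == 0 or c + d == 0:
        raise DegenerateBackgroundError(
            f"degenerate background for term {term!r}: cohort events={a + b}, "
            f"background events={c + d}"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d, term=term, level=level)


def ror(
    ct: ContingencyTable, haldane: bool = False
) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% Wald CI on the log scale.

    ``ROR = ad/bc``; ``CI = exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d))``.
    A zero cell yields ``(nan, nan, nan)`` unless ``haldane=True`` adds
    0.5 to every cell (Haldane–Anscombe correction).
    """
    a, b, c, d = float(ct.a), float(ct.b), float(ct.c), float(ct.d)
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        return (math.nan, math.nan, math.nan)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - Z_95 * se)
    hi = math.exp(math.log(est) + Z_95 * se)
    return (est, lo, hi)


def prr_chi2(
    ct: ContingencyTable, yates: bool = True
) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square statistic.

    ``PRR = [a/(a+b)] / [c/(c+d)]``.  The chi-square is computed over
    the four cells against margin-based expectations; the Yates
    continuity correction (``(|O-E|-0.5)^2/E``, clamped at zero) is
    applied by default.  ``c == 0`` yields ``(nan, chi2)``.
    """
    a, b, c, d = float(ct.a), float(ct.b), float(ct.c), float(ct.d)
    n = a + b + c + d
    if a + b == 0 or c + d == 0 or a + c == 0:
        return (math.nan, math.nan)
    prr = (a / (a + b)) / (c / (c + d)) if c > 0 else math.nan

    observed = np.array([[a, b], [c, d]])
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if (expected == 0).any():
        return (prr, math.nan)
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return (prr, chi2)


class BcpnnVariant(str, enum.Enum):
    #: gamma-approximation IC with Noren's closed-form credibility bound
    NOREN = "NOREN"
    #: original beta/Dirichlet parameterization (1998), Monte-Carlo-free
    #: normal approximation on the IC variance
    ORIGINAL = "ORIGINAL"


def bcpnn_ic(
    ct: ContingencyTable, variant: BcpnnVariant = BcpnnVariant.NOREN
) -> tuple[float, float]:
    """Information component and its lower 95% credibility bound.

    Default (NOREN): ``IC = log2((a+0.5)/(E+0.5))`` with
    ``E=(a+b)(a+c)/N`` and
    ``IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2.4 (a+0.5)^(-3/2)``.

    ORIGINAL: the 1998 beta-parameterized posterior moments of
    ``log2 P(drug, event) / (P(drug) P(event))`` with a normal-
    approximation credibility bound.
    """
    a, n = ct.a, ct.n
    e = ct.expected
    if variant is BcpnnVariant.NOREN:
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.5
        return (ic, ic025)

    # Original variant: independent Dirichlet/beta priors on the margins
    # and the cell, expectation and variance of IC from the 1998 paper.
    a_, b_, c_, d_ = ct.a, ct.b, ct.c, ct.d
    n1 = a_ + b_  # drug margin
    n2 = a_ + c_  # event margin
    alpha1 = beta1 = 1.0  # margin priors
    gamma1 = 1.0
    alpha = alpha1 + n1
    beta = beta1 + n2
    # prior for the cell chosen so that prior E[IC] = 0
    gamma = gamma1 * (n + alpha1 + beta1) ** 2 / ((n1 + alpha1) * (n2 + beta1))
    e_ic = math.log2(
        ((a_ + gamma1) * (n + alpha1) * (n + beta1))
        / ((n + gamma) * (n1 + alpha1) * (n2 + beta1))
    )
    v_ic = (
        (n - a_ + gamma - gamma1) / ((a_ + gamma1) * (1 + n + gamma))
        + (n - n1 + alpha1) / ((n1 + alpha1) * (1 + n + alpha1 + beta1))
        + (n - n2 + beta1) / ((n2 + beta1) * (1 + n + alpha1 + beta1))
    ) / math.log(2) ** 2
    return (e_ic, e_ic - Z_95 * math.sqrt(v_ic))


@dataclass(frozen=True)
class GPSHyperparams:
    """DuMouchel two-component gamma mixture prior on the reporting rate.

    The latent relative reporting rate lambda is a priori
    ``w Gamma(alpha1, beta1) + (1-w) Gamma(alpha2, beta2)`` (shape/rate).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must lie strictly in (0, 1)")


#: DuMouchel's canonical prior, the fallback when the fit fails.
CANONICAL_PRIOR = GPSHyperparams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mixture_log_marginal(
    a: np.ndarray, e: np.ndarray, hp: GPSHyperparams
) -> np.ndarray:
    """log P(a | E, prior): mixture of negative-binomial marginals.

    Poisson(lambda E) with lambda ~ Gamma(alpha, beta) marginalizes to
    NB(r=alpha, p=beta/(beta+E)).
    """
    lp1 = stats.nbinom.logpmf(a, hp.alpha1, hp.beta1 / (hp.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, hp.alpha2, hp.beta2 / (hp.beta2 + e))
    return np.logaddexp(np.log(hp.w) + lp1, np.log1p(-hp.w) + lp2)


def gps_log_marginal_likelihood(
    counts: np.ndarray, expected: np.ndarray, hp: GPSHyperparams
) -> float:
    """Total log marginal likelihood of the corpus under the prior."""
    return float(_mixture_log_marginal(np.asarray(counts), np.asarray(expected), hp).sum())


def fit_gps_prior(
    counts: np.ndarray,
    expected: np.ndarray,
    init: GPSHyperparams = CANONICAL_PRIOR,
    tol: float = 1e-8,
) -> GPSHyperparams:
    """Fit the gamma-mixture prior by maximizing the marginal likelihood.

    Works on the full drug–event corpus (one count and one expectation
    per pair).  The optimization runs on unconstrained transforms (log
    shapes/rates, logit weight) with L-BFGS-B and is deterministic given
    the initial values.  Non-convergence (or a degenerate optimum) falls
    back to the canonical prior with a warning.
    """
    a = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("counts and expected must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("at least two (drug, term) pairs are required")
    if np.any(e <= 0):
        raise ValueError("expectations must be positive")

    def unpack(theta: np.ndarray) -> GPSHyperparams:
        la1, lb1, la2, lb2, logit_w = theta
        return GPSHyperparams(
            math.exp(la1),
            math.exp(lb1),
            math.exp(la2),
            math.exp(lb2),
            1.0 / (1.0 + math.exp(-logit_w)),
        )

    def nll(theta: np.ndarray) -> float:
        try:
            hp = unpack(theta)
        except (OverflowError, ValueError):
            return np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            val = gps_log_marginal_likelihood(a, e, hp)
        return np.inf if not np.isfinite(val) else -val

    theta0 = np.array(
        [
            math.log(init.alpha1),
            math.log(init.beta1),
            math.log(init.alpha2),
            math.log(init.beta2),
            math.log(init.w / (1 - init.w)),
        ]
    )
    bounds = [(-10, 10)] * 4 + [(-8, 8)]
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds, tol=tol
    )
    if not res.success or not np.isfinite(res.fun):
        # one retry from a neutral start before giving up
        res = optimize.minimize(
            nll,
            np.array([0.0, 0.0, 0.0, 0.0, 0.0]),
            method="L-BFGS-B",
            bounds=bounds,
            tol=tol,
        )
    if not res.success or not np.isfinite(res.fun):
        warnings.warn(
            "GPS prior fit did not converge; falling back to the canonical "
            "DuMouchel prior",
            RuntimeWarning,
            stacklevel=2,
        )
        return CANONICAL_PRIOR
    fitted = unpack(res.x)
    # Optimizer contract: never return something worse than the start.
    if -res.fun < gps_log_marginal_likelihood(a, e, init):
        warnings.warn(
            "GPS prior fit ended below its starting likelihood; using the "
            "canonical prior",
            RuntimeWarning,
            stacklevel=2,
        )
        return CANONICAL_PRIOR
    return fitted


def _posterior_mixture(
    a: int, e: float, hp: GPSHyperparams
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Posterior of lambda given count a: weight and two gamma components.

    Returns ``(q1, (shape1, rate1), (shape2, rate2))`` where ``q1`` is
    the posterior weight of component 1.
    """
    lp1 = stats.nbinom.logpmf(a, hp.alpha1, hp.beta1 / (hp.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, hp.alpha2, hp.beta2 / (hp.beta2 + e))
    l1 = math.log(hp.w) + lp1
    l2 = math.log1p(-hp.w) + lp2
    q1 = 1.0 / (1.0 + math.exp(l2 - l1))
    return (
        q1,
        (hp.alpha1 + a, hp.beta1 + e),
        (hp.alpha2 + a, hp.beta2 + e),
    )


def ebgm(ct: ContingencyTable, hp: GPSHyperparams) -> tuple[float, float]:
    """EBGM and EBGM05 for one table under a fitted (or canonical) prior.

    EBGM is the posterior geometric mean ``2^E[log2 lambda | a]``; the
    posterior is the two-component gamma mixture with updated shapes
    ``alpha_k + a``, rates ``beta_k + E`` and data-updated weights.
    EBGM05 is the 5th posterior percentile, found by bisection on the
    mixture CDF.
    """
    return ebgm_from_counts(ct.a, ct.expected, hp)


def ebgm_from_counts(a: int, e: float, hp: GPSHyperparams) -> tuple[float, float]:
    """EBGM/EBGM05 from the observed count and its expectation directly."""
    if e <= 0:
        raise ValueError("expected count must be positive")
    q1, (s1, r1), (s2, r2) = _posterior_mixture(a, e, hp)
    mean_log = q1 * (special.digamma(s1) - math.log(r1)) + (1 - q1) * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm_val = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q1) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    hi = max(
        stats.gamma.ppf(0.05, s1, scale=1 / r1),
        stats.gamma.ppf(0.05, s2, scale=1 / r2),
    )
    while cdf(hi) < 0.05:  # guard against rounding at the bracket edge
        hi *= 2.0
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, 0.0, hi, xtol=1e-12, rtol=1e-12)
    return (ebgm_val, float(ebgm05))


@dataclass(frozen=True)
class SignalThresholds:
    """Positivity thresholds for the four methods (conventional defaults)."""

    ror_min_cases: int = 3
    ror_ci_low: float = 1.0
    prr_min_cases: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass
class SignalResult:
    """All four estimators with intervals and positivity flags for one term."""

    term: str
    level: TermLevel
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ebgm: float
    ebgm05: float
    ic: float
    ic025: float
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_mgps: bool = False
    flag_any: bool = False


def flag_signals(
    results: list[SignalResult], thresholds: SignalThresholds | None = None
) -> list[SignalResult]:
    """Apply the positivity thresholds; ``flag_any`` is the OR of the four."""
    th = thresholds or SignalThresholds()
    for r in results:
        r.flag_ror = bool(
            r.a >= th.ror_min_cases
            and math.isfinite(r.ror_lo)
            and r.ror_lo > th.ror_ci_low
        )
        r.flag_prr = bool(
            r.a >= th.prr_min_cases
            and math.isfinite(r.prr)
            and r.prr >= th.prr_min
            and math.isfinite(r.chi2)
            and r.chi2 >= th.chi2_min
        )
        r.flag_bcpnn = bool(math.isfinite(r.ic025) and r.ic025 > th.ic025_min)
        r.flag_mgps = bool(math.isfinite(r.ebgm05) and r.ebgm05 > th.ebgm05_min)
        r.flag_any = r.flag_ror or r.flag_prr or r.flag_bcpnn or r.flag_mgps
    return results


def events_to_soc(
    events: set[tuple[str, str]], pt_to_soc: dict[str, str]
) -> set[tuple[str, str]]:
    """Map (report, PT) events to distinct (report, SOC) events.

    A report contributes at most once per SOC regardless of how many of
    its PTs map there; PTs absent from the map are dropped (logged).
    """
    out: set[tuple[str, str]] = set()
    unmapped: set[str] = set()
    for rid, pt in events:
        soc = pt_to_soc.get(pt)
        if soc is None:
            unmapped.add(pt)
        else:
            out.add((rid, soc))
    if unmapped:
        logger.info("events_to_soc: %d PT(s) had no SOC mapping", len(unmapped))
    return out


def evaluate_terms(
    cohort_events: set[tuple[str, str]],
    background_events: set[tuple[str, str]],
    level: TermLevel = TermLevel.PT,
    prior: GPSHyperparams | None = None,
    thresholds: SignalThresholds | None = None,
    bcpnn_variant: BcpnnVariant = BcpnnVariant.NOREN,
    yates: bool = True,
    haldane: bool = False,
) -> list[SignalResult]:
    """Compute all four statistics for every term in the cohort.

    ``prior=None`` uses the canonical DuMouchel prior (the target-drug
    cohort alone cannot support a corpus-wide prior fit).  Results come
    back sorted by descending case count, ties alphabetical.
    """
    hp = prior or CANONICAL_PRIOR
    terms = sorted({t for _, t in cohort_events})
    results: list[SignalResult] = []
    for term in terms:
        ct = build_contingency(cohort_events, background_events, term, level)
        ror_est, ror_lo, ror_hi = ror(ct, haldane=haldane)
        prr_val, chi2_val = prr_chi2(ct, yates=yates)
        ic, ic025 = bcpnn_ic(ct, variant=bcpnn_variant)
        ebgm_val, ebgm05_val = ebgm(ct, hp)
        results.append(
            SignalResult(
                term=term,
                level=level,
                a=ct.a,
                ror=ror_est,
                ror_lo=ror_lo,
                ror_hi=ror_hi,
                prr=prr_val,
                chi2=chi2_val,
                ebgm=ebgm_val,
                ebgm05=ebgm05_val,
                ic=ic,
                ic025=ic025,
            )
        )
    results.sort(key=lambda r: (-r.a, r.term))
    return flag_signals(results, thresholds)
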