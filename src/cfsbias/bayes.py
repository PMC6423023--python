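"""Default (JZS) Bayes factors for t designs, two-sided and directional.

The Bayes factor against the point null compares the marginal likelihood of
the observed t statistic under a Cauchy(0, r) prior on the standardized
effect size delta with its likelihood at delta = 0:

    BF_10 = [ integral f_nu(t; delta * sqrt(n_eff)) dCauchy(delta; 0, r) ]
            / f_nu(t; 0)

where ``f_nu(.; mu)`` is the noncentral-t density with ``nu`` degrees of
freedom.  Directional variants (BF_+0 / BF_-0) place the full prior mass on
one half-line (truncated, renormalized half-Cauchy), matching the convention
of standard Bayesian t-test software.  The default prior scale is r = 0.707
(sqrt(2)/2).

Numerics: the substitution ``delta = r * tan(theta)`` maps the heavy-tailed
Cauchy measure to the uniform measure on (-pi/2, pi/2), so the integrand is
bounded and smooth; it is integrated by Gauss-Legendre rules of doubling
order until two successive orders agree to relative tolerance 1e-8.  All
densities are evaluated in log space and shifted by their maximum before
exponentiation, so Bayes factors of astronomical magnitude (|t| > 40) come
out with a finite ``log_bf`` even when ``bf`` itself overflows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

DEFAULT_PRIOR_SCALE = 0.707

_DIRECTIONS = ("two_sided", "positive", "negative")
_THETA_EDGE = np.pi / 2 - 1e-9  # open interval: tan() stays finite


class QuadratureWarning(UserWarning):
    """Integration did not reach the requested relative tolerance."""


def classify_evidence(bf: float) -> str:
    """Map a Bayes factor onto the conventional evidence bands.

    BF >= 3 is substantial evidence for the alternative, BF <= 1/3 substantial
    evidence for the null, anything between is inconclusive.  Boundary values
    count as substantial.
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if bf >= 3.0:
        return "substantial_alternative"
    if bf <= 1.0 / 3.0:
        return "substantial_null"
    return "inconclusive"


@dataclass(frozen=True)
class BayesFactorResult:
    """A JZS Bayes factor together with the inputs that produced it."""

    bf: float
    log_bf: float
    direction: str
    t: float
    df: float
    n_eff: float
    r: float

    @property
    def bf_null(self) -> float:
        """The reciprocal (evidence for the null), BF_0+ style."""
        return float(np.exp(-self.log_bf))

    @property
    def evidence(self) -> str:
        return classify_evidence(self.bf if np.isfinite(self.bf) else np.exp(min(self.log_bf, 700.0)))


def _log_marginal(t: float, df: float, n_eff: float, r: float,
                  lo: float, hi: float, rtol: float = 1e-8) -> float:
    """log integral of f_df(t; r*tan(theta)*sqrt(n_eff)) over theta in (lo, hi)."""
    sqrt_n = np.sqrt(n_eff)
    prev = None
    for order in (65, 129, 257, 513, 1025, 2049):
        x, w = leggauss(order)
        theta = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        with warnings.catch_warnings():
            # extreme noncentralities near the domain edge underflow inside
            # scipy's quadrature; they contribute nothing to the integral
            warnings.simplefilter("ignore", RuntimeWarning)
            logf = stats.nct.logpdf(t, df, r * np.tan(theta) * sqrt_n)
        logf = np.where(np.isfinite(logf), logf, -np.inf)
        m = logf.max()
        val = m + np.log(0.5 * (hi - lo) * np.sum(w * np.exp(logf - m)))
        if prev is not None and abs(val - prev) <= rtol * max(abs(val), 1.0):
            return val
        prev = val
    warnings.warn("quadrature tolerance unmet; returning best estimate",
                  QuadratureWarning, stacklevel=3)
    return val


def _jzs_bf(t: float, df: float, n_eff: float, r: float, direction: str) -> BayesFactorResult:
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if r <= 0:
        raise ValueError("prior scale r must be positive")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")

    if direction == "two_sided":
        lo, hi, log_norm = -_THETA_EDGE, _THETA_EDGE, -np.log(np.pi)
    elif direction == "positive":
        lo, hi, log_norm = 0.0, _THETA_EDGE, np.log(2.0 / np.pi)
    else:
        lo, hi, log_norm = -_THETA_EDGE, 0.0, np.log(2.0 / np.pi)

    log_num = log_norm + _log_marginal(t, df, n_eff, r, lo, hi)
    log_den = stats.t.logpdf(t, df)
    log_bf = float(log_num - log_den)
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))
    return BayesFactorResult(bf=bf, log_bf=log_bf, direction=direction,
                             t=float(t), df=float(df), n_eff=float(n_eff), r=float(r))


def jzs_bf_one_sample(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE,
                      direction: str = "two_sided") -> BayesFactorResult:
    """JZS Bayes factor for a one-sample (or paired) t statistic.

    ``n`` is the number of subjects (pairs); degrees of freedom are ``n - 1``
    and the effective sample size entering the noncentrality is ``n``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return _jzs_bf(t, df=n - 1, n_eff=n, r=r, direction=direction)


def jzs_bf_two_sample(t: float, n1: int, n2: int, r: float = DEFAULT_PRIOR_SCALE,
                      direction: str = "two_sided") -> BayesFactorResult:
    """JZS Bayes factor for an independent-samples t statistic.

    Degrees of freedom ``n1 + n2 - 2``; effective sample size
    ``n1 * n2 / (n1 + n2)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    return _jzs_bf(t, df=n1 + n2 - 2, n_eff=n1 * n2 / (n1 + n2), r=r, direction=direction)


def one_sample_t(x) -> tuple:
    """(t, n) of a one-sample t test of ``mean(x) == 0``.

    A constant-zero sample is zero signal (t = 0); a constant nonzero sample
    has no finite t and is rejected.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == 0:
            return 0.0, n
        raise ValueError("zero-variance sample with nonzero mean: t undefined")
    return float(x.mean() / (sd / np.sqrt(n))), n


def t_from_summary(mean: float, sd: float, n: int) -> float:
    """One-sample t from a printed mean / SD / n summary."""
    return mean / (sd / np.sqrt(n))


def t_from_two_summaries(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> float:
    """Independent-samples t (pooled variance) from two printed summaries."""
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    return (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def bf_from_effects(d, r: float = DEFAULT_PRIOR_SCALE,
                    direction: str = "positive") -> BayesFactorResult:
    """Directional one-sample BF on a vector of per-participant effects ``d``.

    This is the paired-test route: the paired design reduces to a one-sample
    test on the per-participant normalized differences.
    """
    t, n = one_sample_t(d)
    return jzs_bf_one_sample(t, n, r=r, direction=direction)
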