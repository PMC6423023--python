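"""AIC comparison of monotonic vs non-monotonic repetition profiles.

Four regression families are fitted to a per-repetition profile
``y(r), r = 1..6``: two monotonic (linear, exponential decay-to-asymptote
``y = a + b * exp(-c * (r - 1))``) and two non-monotonic (quadratic, cubic).
Fit quality is compared by the Gaussian least-squares AIC

    AIC = n * ln(RSS / n) + 2k

where ``k`` counts the mean-structure coefficients plus one for the residual
variance (linear 3, exponential 4, quadratic 4, cubic 5).  Model adjudication
uses the Akaike relative likelihood RL(a over b) = exp(0.5 * (AIC_b - AIC_a)),
the estimated ratio of probabilities that each model minimizes information
loss; only AIC *differences* enter it, so the additive convention cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

FAMILIES = ("linear", "exponential", "quadratic", "cubic")
_K = {"linear": 3, "exponential": 4, "quadratic": 4, "cubic": 5}
_RSS_GUARD = 1e-12

#: multi-start grid for the exponential rate c; the near-zero starts let the
#: family reach its linear (c -> 0) limit on straight-line profiles
_C_GRID = np.concatenate(([0.001, 0.005, 0.01, 0.02, 0.05],
                          np.arange(0.1, 3.01, 0.1)))


@dataclass(frozen=True)
class ModelFit:
    family: str
    params: tuple
    k: int
    rss: float
    n_points: int
    aic: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "exponential":
            a, b, c = self.params
            return a + b * np.exp(-c * (x - 1.0))
        return np.polyval(self.params, x)


@dataclass(frozen=True)
class RelativeLikelihood:
    model_a: str
    model_b: str
    rl: float

    @property
    def rounded(self) -> int:
        """Nearest-integer ratio for report tables."""
        return int(round(self.rl))


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, _RSS_GUARD) / n) + 2 * k


def _fit_exponential(x: np.ndarray, y: np.ndarray):
    """Best-of-starts nonlinear least squares for y = a + b*exp(-c*(x-1)).

    For each rate on the start grid, (a, b) are solved by linear least
    squares; the best start is then polished jointly.  All-starts failure is
    reported, not silently ignored.
    """
    best = None
    for c in _C_GRID:
        basis = np.column_stack([np.ones_like(x), np.exp(-c * (x - 1.0))])
        (a, b), *_ = np.linalg.lstsq(basis, y, rcond=None)
        rss = float(np.sum((y - basis @ [a, b]) ** 2))
        if best is None or rss < best[0]:
            best = (rss, a, b, c)

    def resid(p):
        return p[0] + p[1] * np.exp(-p[2] * (x - 1.0)) - y

    sol = least_squares(resid, x0=best[1:], bounds=([-np.inf, -np.inf, 1e-8],
                                                    [np.inf, np.inf, 50.0]))
    if not sol.success and best is None:
        raise RuntimeError("exponential fit failed to converge from any start")
    params = tuple(sol.x) if sol.success and 2 * sol.cost <= best[0] else best[1:]
    rss = float(np.sum(resid(params) ** 2))
    return params, rss


def fit_profile(y, family: str) -> ModelFit:
    """Fit one regression family to a repetition profile ``y`` at x = 1..len(y)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("profile contains non-finite values")
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    x = np.arange(1, y.size + 1, dtype=float)

    if family == "exponential":
        params, rss = _fit_exponential(x, y)
    else:
        deg = {"linear": 1, "quadratic": 2, "cubic": 3}[family]
        coef = np.polyfit(x, y, deg)
        rss = float(np.sum((y - np.polyval(coef, x)) ** 2))
        params = tuple(coef)

    k = _K[family]
    return ModelFit(family=family, params=params, k=k, rss=rss,
                    n_points=y.size, aic=float(_aic(rss, y.size, k)))


def relative_likelihood(aic_a: float, aic_b: float,
                        model_a: str = "a", model_b: str = "b") -> RelativeLikelihood:
    """Akaike relative likelihood of model a over model b from their AICs."""
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise ValueError("AIC values must be finite")
    return RelativeLikelihood(model_a=model_a, model_b=model_b,
                              rl=float(np.exp(0.5 * (aic_b - aic_a))))


def compare_families(y) -> tuple:
    """Fit all four families; rank by AIC and compute pairwise RLs.

    Returns ``(fits, rl_table)``: fits sorted by AIC ascending (ties broken
    by smaller k, then fixed family order) and a DataFrame of pairwise
    relative likelihoods of the row model over the column model.
    """
    fits = [fit_profile(y, fam) for fam in FAMILIES]
    order = {f: i for i, f in enumerate(FAMILIES)}
    fits.sort(key=lambda m: (m.aic, m.k, order[m.family]))
    rl = pd.DataFrame(
        {b.family: [relative_likelihood(a.aic, b.aic).rl for a in fits] for b in fits},
        index=[a.family for a in fits],
    )
    return fits, rl


def fits_table(fits) -> pd.DataFrame:
    """Model table (family, k, rss, aic) mirroring a goodness-of-fit report."""
    return pd.DataFrame(
        [{"family": m.family, "k": m.k, "rss": m.rss, "aic": m.aic} for m in fits]
    )
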