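"""Gaussian density optima by quadratic logistic regression, with Fieller CIs.

A Gaussian response on a gradient x is equivalent to a quadratic on the
logit scale:

    logit mu(x) = b0 + b1 x + b2 x^2,        b2 < 0,

so fitting a binomial GLM of scaled densities on (x, x^2) estimates the
optimum as the peak location

    x_opt = -b1 / (2 b2).

Being a ratio of correlated coefficient estimates, the optimum's confidence
interval comes from Fieller's theorem: the set of u where
(b1 + 2 b2 u)^2 <= z^2 Var(b1 + 2 b2 u), a quadratic inequality

    A u^2 + B u + C <= 0,
    A = 4 b2^2 - 4 z^2 v22,  B = 4 b1 b2 - 4 z^2 v12,  C = b1^2 - z^2 v11,

with v the Wald covariance of (b1, b2) and z the two-sided normal quantile
(z = 1.4051 at the 84% level used for overlap testing).  When A <= 0 or the
discriminant is negative the confidence set is unbounded and the species is
flagged rather than assigned a spurious interval.  Bounds are reported
verbatim, even when absurd (far outside the sampled gradient).

Eligibility screening mirrors field practice: a unimodal (HOF IV/V)
classification, >= 10 profile points, occupancy at >= 3 sites, and an
optimum at least 100 m inside the observed elevational domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

DEFAULT_CI_LEVEL = 0.84
DEFAULT_MIN_POINTS = 10
DEFAULT_MIN_OCCUPANCY = 3
DEFAULT_INTERIOR_MARGIN = 100.0

__all__ = [
    "GaussianFit", "EligibilityReport", "fit_gaussian_logit", "optimum",
    "fieller_interval", "check_eligibility", "DEFAULT_CI_LEVEL",
    "DEFAULT_MIN_POINTS", "DEFAULT_MIN_OCCUPANCY", "DEFAULT_INTERIOR_MARGIN",
]


@dataclass(frozen=True)
class GaussianFit:
    """Quadratic-logit (Gaussian) fit of one species x region profile."""

    species_id: str
    region: str
    b0: float
    b1: float
    b2: float
    coef_covariance: np.ndarray    # 3x3, order (b0, b1, b2), gradient units
    optimum: float                 # m; nan when b2 >= 0
    ci_low: float                  # nan when the Fieller set is not an interval
    ci_high: float
    ci_level: float
    ci_bounded: bool
    pct_deviance_explained: float
    n_sites: int
    converged: bool = True

    @property
    def has_interior_optimum(self) -> bool:
        return self.b2 < 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = self.b0 + self.b1 * x + self.b2 * x**2
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


@dataclass(frozen=True)
class EligibilityReport:
    species_id: str
    unimodal: bool
    enough_points: bool
    occupancy_ok: bool
    interior_optimum: bool

    @property
    def eligible(self) -> bool:
        return self.unimodal and self.enough_points and self.occupancy_ok and self.interior_optimum


def fit_gaussian_logit(
    x,
    y,
    *,
    species_id: str = "",
    region: str = "",
    weights=None,
    ci_level: float = DEFAULT_CI_LEVEL,
    min_points: int = DEFAULT_MIN_POINTS,
) -> GaussianFit:
    """Binomial GLM logit(mu) = b0 + b1 x + b2 x^2 by IRLS.

    ``y`` are proportions of maximum density in [0, 1] (non-integer allowed,
    quasi-likelihood sense); ``weights`` are optional binomial trial counts
    per point (``var_weights``), needed for properly scaled covariances when
    the data really are binomial counts.  The gradient is internally scaled
    to [0, 1] for numerical stability; all reported quantities are on the
    original (metre) axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_points:
        raise ValueError(f"need >= {min_points} points, got {x.size}")
    if np.all(y == y[0]):
        raise ValueError("degenerate profile: all proportions equal")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")

    lo, span = float(x.min()), float(x.max() - x.min())
    if span == 0:
        raise ValueError("gradient values are all equal")
    u = (x - lo) / span
    X = np.column_stack([np.ones_like(u), u, u**2])

    kwargs = {"family": sm.families.Binomial()}
    if weights is not None:
        kwargs["var_weights"] = np.asarray(weights, dtype=float)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, **kwargs).fit(maxiter=200)
            converged = bool(res.converged)
        except Exception:
            return GaussianFit(species_id, region, np.nan, np.nan, np.nan,
                               np.full((3, 3), np.nan), np.nan, np.nan, np.nan,
                               ci_level, False, np.nan, int(x.size), False)

    c = np.asarray(res.params, dtype=float)
    cov_c = np.asarray(res.cov_params(), dtype=float)
    # back-transform coefficients (and covariance) from u = (x-lo)/span to x
    A = np.array([
        [1.0, -lo / span, lo**2 / span**2],
        [0.0, 1.0 / span, -2.0 * lo / span**2],
        [0.0, 0.0, 1.0 / span**2],
    ])
    b = A @ c
    cov_b = A @ cov_c @ A.T

    null_dev = float(res.null_deviance)
    pct_dev = 100.0 * (1.0 - float(res.deviance) / null_dev) if null_dev > 0 else np.nan

    b0, b1, b2 = (float(v) for v in b)
    if b2 < 0:
        opt = -b1 / (2.0 * b2)
        lo_ci, hi_ci, bounded = fieller_interval(b1, b2, cov_b[1:, 1:], level=ci_level)
    else:
        opt, lo_ci, hi_ci, bounded = np.nan, np.nan, np.nan, False

    return GaussianFit(
        species_id=species_id, region=region,
        b0=b0, b1=b1, b2=b2, coef_covariance=cov_b,
        optimum=float(opt), ci_low=float(lo_ci), ci_high=float(hi_ci),
        ci_level=float(ci_level), ci_bounded=bool(bounded),
        pct_deviance_explained=float(pct_dev),
        n_sites=int(x.size), converged=converged,
    )


def optimum(fit: GaussianFit) -> float:
    """Peak location -b1/(2 b2) of a Gaussian-logit fit; requires b2 < 0."""
    if fit.b2 >= 0:
        raise ValueError("no interior optimum: b2 >= 0")
    return -fit.b1 / (2.0 * fit.b2)


def fieller_interval(
    b1: float, b2: float, cov: np.ndarray, *, level: float = DEFAULT_CI_LEVEL
) -> tuple[float, float, bool]:
    """Fieller confidence set for the ratio -b1/(2 b2).

    ``cov`` is the 2x2 covariance of (b1, b2).  Returns ``(low, high,
    bounded)``; ``bounded`` is False (with nan bounds) when the confidence
    set is the whole line, a complement of an interval, or otherwise not a
    finite interval (A <= 0 or negative discriminant).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    v11, v12, v22 = float(cov[0, 0]), float(cov[0, 1]), float(cov[1, 1])
    A = 4.0 * b2**2 - 4.0 * z**2 * v22
    B = 4.0 * b1 * b2 - 4.0 * z**2 * v12
    C = b1**2 - z**2 * v11
    disc = B**2 - 4.0 * A * C
    if A <= 0 or disc <= 0:
        return (np.nan, np.nan, False)
    root = np.sqrt(disc)
    lo = (-B - root) / (2.0 * A)
    hi = (-B + root) / (2.0 * A)
    return (float(min(lo, hi)), float(max(lo, hi)), True)


def check_eligibility(
    species_id: str,
    *,
    model_type: str,
    n_points: int,
    n_occupied_sites: int,
    fit: GaussianFit | None,
    domain_bounds: tuple[float, float],
    min_points: int = DEFAULT_MIN_POINTS,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
    interior_margin: float = DEFAULT_INTERIOR_MARGIN,
) -> EligibilityReport:
    """Screen a species for optimum comparison.

    ``domain_bounds`` is the observed elevational span of the region; the
    interior test requires the fitted optimum to sit at least
    ``interior_margin`` metres inside both bounds (and to exist at all).
    """
    unimodal = model_type in ("IV", "V")
    enough = n_points >= min_points
    occupancy = n_occupied_sites >= min_occupancy
    lo, hi = domain_bounds
    interior = (
        fit is not None
        and fit.converged
        and fit.has_interior_optimum
        and np.isfinite(fit.optimum)
        and (lo + interior_margin) <= fit.optimum <= (hi - interior_margin)
    )
    return EligibilityReport(
        species_id=species_id,
        unimodal=bool(unimodal),
        enough_points=bool(enough),
        occupancy_ok=bool(occupancy),
        interior_optimum=bool(interior),
    )
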