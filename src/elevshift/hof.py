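"""Huisman-Olff-Fresco (HOF) hierarchy of species response curves.

Five nested bounded-logistic shapes describe how a species' relative
density mu(x) in [0, 1] varies along a standardized gradient x in [0, 1]:

    I   flat        mu = 1/(1+e^a)
    II  monotonic   mu = 1/(1+e^(a+bx))
    III plateau     mu = 1/(1+e^(a+bx)) * 1/(1+e^c)
    IV  gaussian    mu = 1/(1+e^(a+bx)) * 1/(1+e^(c-bx))   (symmetric peak)
    V   skewed      mu = 1/(1+e^(a+bx)) * 1/(1+e^(c-dx))

Parameters minimize the binomial deviance of the observed proportions
(density scaled to each species' maximum); the winning type has the lowest
AIC = deviance + 2k, ties broken toward fewer parameters.  Species whose
best type is IV or V have a well-defined density optimum and continue to
optimum estimation; the rest are screened out.

The deviance surfaces are multimodal, so each type is optimized from
several seeded random starts plus warm starts that embed the next-simpler
type's optimum (I in II via b=0, II in IV via c -> -inf, II/IV in V via
d=0 / d=b); the warm starts also guarantee the nesting inequality
deviance(V) <= deviance(IV) <= deviance(II) <= deviance(I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

MODEL_TYPES = ("I", "II", "III", "IV", "V")
N_PARAMS = {"I": 1, "II": 2, "III": 3, "IV": 3, "V": 4}
_BOUND = 100.0
_EPS = 1e-10

__all__ = ["MODEL_TYPES", "N_PARAMS", "HOFFit", "scale_to_proportion",
           "hof_curve", "binomial_deviance", "fit_hof", "classify_response"]


@dataclass(frozen=True)
class HOFFit:
    """One HOF model fitted to a species' scaled density profile."""

    species_id: str
    model_type: str
    params: tuple[float, ...]
    scaling_max: float        # density that was mapped to proportion 1
    x_offset: float           # gradient standardisation: u = (x - offset)/scale
    x_scale: float
    deviance: float
    aic: float
    n_points: int
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        """Fitted proportions at gradient values on the original axis."""
        u = (np.asarray(x, dtype=float) - self.x_offset) / self.x_scale
        return hof_curve(self.model_type, self.params, u)

    def optimum_x(self) -> float:
        """Gradient value (original axis) at which the fitted curve peaks.

        Closed form for type IV (peak at u = (c-a)/(2b)); fine-grid argmax
        for the other types (types I-III peak at a domain edge).
        """
        if self.model_type == "IV":
            a, b, c = self.params
            u_star = np.clip((c - a) / (2.0 * b), 0.0, 1.0) if b != 0 else 0.5
        else:
            u = np.linspace(0.0, 1.0, 4001)
            u_star = u[int(np.argmax(hof_curve(self.model_type, self.params, u)))]
        return float(self.x_offset + self.x_scale * u_star)


def scale_to_proportion(densities) -> np.ndarray:
    """Express densities as proportions of the species' maximum.

    The maximum maps to exactly 1; an all-zero profile (species absent)
    raises, so callers can flag and exclude the species.
    """
    d = np.asarray(densities, dtype=float)
    if d.size == 0 or np.any(d < 0):
        raise ValueError("densities must be non-empty and non-negative")
    peak = d.max()
    if peak == 0:
        raise ValueError("species absent: all densities zero")
    return d / peak


def hof_curve(model_type: str, params, u) -> np.ndarray:
    """Evaluate a HOF curve on the standardized gradient u (usually [0,1])."""
    u = np.asarray(u, dtype=float)
    p = np.asarray(params, dtype=float)

    def logistic(t):
        return 1.0 / (1.0 + np.exp(np.clip(t, -500, 500)))

    if model_type == "I":
        (a,) = p
        return np.full_like(u, logistic(a))
    if model_type == "II":
        a, b = p
        return logistic(a + b * u)
    if model_type == "III":
        a, b, c = p
        return logistic(a + b * u) * logistic(c)
    if model_type == "IV":
        a, b, c = p
        return logistic(a + b * u) * logistic(c - b * u)
    if model_type == "V":
        a, b, c, d = p
        return logistic(a + b * u) * logistic(c - d * u)
    raise ValueError(f"unknown HOF model type: {model_type!r}")


def binomial_deviance(y, mu) -> float:
    """Binomial deviance of proportions y under fitted mu, unit weights."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _EPS, 1.0 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1.0 - y) * np.log((1.0 - y) / (1.0 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _standardize(x) -> tuple[np.ndarray, float, float]:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("gradient values are all equal")
    return (x - lo) / (hi - lo), float(lo), float(hi - lo)


def _warm_starts(model_type: str, simpler: dict[str, "HOFFit"]) -> list[np.ndarray]:
    """Embed already-fitted simpler types into this type's parameter space."""
    starts = []
    if model_type == "II" and "I" in simpler:
        (a,) = simpler["I"].params
        starts.append(np.array([a, 0.0]))
    if model_type == "III" and "II" in simpler:
        a, b = simpler["II"].params
        starts.append(np.array([a, b, -_BOUND]))
    if model_type == "IV" and "II" in simpler:
        a, b = simpler["II"].params
        starts.append(np.array([a, b, -_BOUND]))
    if model_type == "V":
        if "IV" in simpler:
            a, b, c = simpler["IV"].params
            starts.append(np.array([a, b, c, b]))
        if "II" in simpler:
            a, b = simpler["II"].params
            starts.append(np.array([a, b, -_BOUND, 0.0]))
    return starts


def fit_hof(
    x,
    y,
    model_type: str,
    *,
    species_id: str = "",
    scaling_max: float = 1.0,
    n_restarts: int = 20,
    seed: int = 0,
    extra_starts: list[np.ndarray] | None = None,
    min_points: int = 10,
) -> HOFFit:
    """Fit one HOF type by deviance minimisation with seeded restarts."""
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown HOF model type: {model_type!r}")
    y = np.asarray(y, dtype=float)
    if y.size < min_points:
        raise ValueError(f"need >= {min_points} points, got {y.size}")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    u, x_off, x_scale = _standardize(x)
    k = N_PARAMS[model_type]

    def objective(p):
        return binomial_deviance(y, hof_curve(model_type, p, u))

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = list(extra_starts or [])
    # deterministic heuristic start near the empirical peak
    ybar = float(np.clip(y.mean(), 0.01, 0.99))
    a0 = np.log(1.0 / ybar - 1.0)
    heuristics = {
        "I": [a0], "II": [a0, 0.0], "III": [a0, 0.0, -5.0],
        "IV": [a0, 5.0, a0 + 5.0], "V": [a0, 5.0, a0 + 5.0, 5.0],
    }
    starts.append(np.array(heuristics[model_type], dtype=float))
    for _ in range(n_restarts):
        p = rng.uniform(-15.0, 15.0, size=k)
        if k >= 2:
            p[1] = rng.uniform(-40.0, 40.0)
        if model_type == "V":
            p[3] = rng.uniform(-40.0, 40.0)
        starts.append(p)

    bounds = [(-_BOUND, _BOUND)] * k
    best = None
    any_ok = False
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, dtype=float), -_BOUND, _BOUND)
        res = minimize(objective, p0, method="L-BFGS-B", bounds=bounds)
        cand = (float(res.fun), tuple(float(v) for v in res.x))
        any_ok = any_ok or bool(res.success)
        if best is None or cand[0] < best[0]:
            best = cand
    dev, params = best
    if not np.isfinite(dev) or not any_ok:
        return HOFFit(species_id, model_type, params, scaling_max, x_off,
                      x_scale, float("inf"), float("inf"), int(y.size), False)
    return HOFFit(
        species_id=species_id,
        model_type=model_type,
        params=params,
        scaling_max=scaling_max,
        x_offset=x_off,
        x_scale=x_scale,
        deviance=dev,
        aic=dev + 2.0 * k,
        n_points=int(y.size),
        converged=True,
    )


def classify_response(
    x,
    y,
    *,
    species_id: str = "",
    scaling_max: float = 1.0,
    n_restarts: int = 20,
    seed: int = 0,
    min_points: int = 10,
) -> tuple[HOFFit, dict[str, HOFFit]]:
    """Fit all five HOF types and select the lowest-AIC model.

    Returns ``(best, fits_by_type)``.  Ties in AIC are broken toward the
    simpler model (fewer parameters), deterministically.  Flagged
    (non-converged) fits carry infinite AIC; if every type is flagged the
    best fit has model_type ``"unfit"``.
    """
    fits: dict[str, HOFFit] = {}
    for mt in MODEL_TYPES:
        fits[mt] = fit_hof(
            x, y, mt,
            species_id=species_id, scaling_max=scaling_max,
            n_restarts=n_restarts, seed=seed,
            extra_starts=_warm_starts(mt, fits), min_points=min_points,
        )
    finite = [f for f in fits.values() if np.isfinite(f.aic)]
    if not finite:
        u, x_off, x_scale = _standardize(x)
        best = HOFFit(species_id, "unfit", (), scaling_max, x_off, x_scale,
                      float("inf"), float("inf"), len(np.asarray(y)), False)
        return best, fits
    best = min(finite, key=lambda f: (round(f.aic, 9), N_PARAMS[f.model_type]))
    return best, fits
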