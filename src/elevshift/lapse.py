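"""Linear temperature-elevation (lapse) models and isotherm translation.

Each subregion x temperature parameter (MAT, T_max, T_min) gets an ordinary
least-squares fit T(z) = a + b z with b < 0.  Two such models support the
space-for-time step:

* the intercept difference a_north - a_south is the temperature offset
  between regions at equal elevation;
* translating a southern elevation along an isotherm gives the northern
  elevation with the same temperature,
  z_north = (a_s + b_s z - a_n) / b_n;
* for parallel lapses the expected upslope displacement of any isotherm is
  (a_n - a_s) / (-b); when the lapses cross, a single number is ill-defined
  and the displacement is reported at a reference elevation instead.

Standard errors of the displacement come from first-order (delta-method)
propagation of the two fits' coefficient covariances, treated as
independent because the regions use disjoint sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LapseModel", "ParallelismTest", "DisplacementPrediction",
    "fit_lapse", "test_parallelism", "predict_displacement",
    "translate_elevation", "temperature_at",
]


@dataclass(frozen=True)
class LapseModel:
    """OLS fit of temperature on elevation for one region x parameter."""

    region: str
    parameter: str
    intercept: float          # degC at sea level
    slope: float              # degC per metre (negative)
    coef_covariance: np.ndarray   # 2x2, order (intercept, slope)
    n_points: int
    residual_sd: float
    elevation_range: tuple[float, float]


@dataclass(frozen=True)
class ParallelismTest:
    t: float
    p: float
    parallel: bool
    alpha: float


@dataclass(frozen=True)
class DisplacementPrediction:
    """Expected northern upslope displacement for one temperature parameter."""

    parameter: str
    temp_offset: float        # degC, intercept_north - intercept_south
    se_temp_offset: float
    displacement: float       # m, expected northern upshift
    se_displacement: float
    parallel: bool
    reference_elevation: float | None   # m, set when lapses are not parallel


def fit_lapse(
    elevations,
    temperatures,
    *,
    region: str,
    parameter: str,
    require_negative_slope: bool = True,
) -> LapseModel:
    """OLS temperature ~ elevation for one region and temperature parameter."""
    z = np.asarray(elevations, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if z.size != t.size:
        raise ValueError("elevations and temperatures must have equal length")
    if np.unique(z).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct elevations")
    if z.size < 3:
        raise ValueError("need >= 3 points to estimate a residual variance")
    X = sm.add_constant(z)
    res = sm.OLS(t, X).fit()
    slope = float(res.params[1])
    if require_negative_slope and slope >= 0:
        raise ValueError(
            f"lapse slope {slope:.3g} >= 0 for {parameter}/{region}: "
            "temperature gradients must cool with elevation"
        )
    return LapseModel(
        region=region,
        parameter=parameter,
        intercept=float(res.params[0]),
        slope=slope,
        coef_covariance=np.asarray(res.cov_params()),
        n_points=int(z.size),
        residual_sd=float(np.sqrt(res.scale)),
        elevation_range=(float(z.min()), float(z.max())),
    )


def test_parallelism(
    elev_south, temp_south, elev_north, temp_north, *, alpha: float = 0.05
) -> ParallelismTest:
    """Interaction test: temperature ~ elevation * region on the pooled data.

    The t statistic and p-value are those of the elevation x region
    interaction coefficient (region coded north=1), i.e. the difference of
    slopes; ``parallel`` is True when p >= alpha.
    """
    zs = np.asarray(elev_south, dtype=float)
    zn = np.asarray(elev_north, dtype=float)
    ts = np.asarray(temp_south, dtype=float)
    tn = np.asarray(temp_north, dtype=float)
    if np.unique(zs).size < 2 or np.unique(zn).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct elevations per region")
    z = np.concatenate([zs, zn])
    y = np.concatenate([ts, tn])
    north = np.concatenate([np.zeros(zs.size), np.ones(zn.size)])
    X = np.column_stack([np.ones(z.size), z, north, z * north])
    res = sm.OLS(y, X).fit()
    t_int = float(res.tvalues[3])
    p_int = float(res.pvalues[3])
    return ParallelismTest(t=t_int, p=p_int, parallel=bool(p_int >= alpha), alpha=alpha)


def temperature_at(model: LapseModel, elevation: float) -> float:
    """Predicted temperature at an elevation under a fitted lapse."""
    return model.intercept + model.slope * elevation


def translate_elevation(z_south, lapse_south: LapseModel, lapse_north: LapseModel):
    """Northern elevation on the same isotherm as a southern elevation.

    Solves T_north(z_north) = T_south(z_south):
    z_north = (a_s + b_s z_s - a_n) / b_n.
    """
    if lapse_north.slope >= 0:
        raise ValueError("northern lapse slope must be negative")
    z = np.asarray(z_south, dtype=float)
    out = (lapse_south.intercept + lapse_south.slope * z - lapse_north.intercept) / lapse_north.slope
    return float(out) if np.isscalar(z_south) else out


def predict_displacement(
    lapse_south: LapseModel,
    lapse_north: LapseModel,
    *,
    parallel: bool = True,
    reference_elevation: float | None = None,
) -> DisplacementPrediction:
    """Expected northern upslope displacement with a delta-method SE.

    Parallel case: displacement = (a_n - a_s) / (-b̄) with b̄ the mean of the
    two fitted slopes (equal to either when exactly parallel).  Non-parallel
    case: displacement of the isotherm through ``reference_elevation``
    (default: midpoint of the pooled fitted elevation range),
    z_n(T_s(z_ref)) - z_ref.  The SE propagates both fits' coefficient
    covariances to first order, treating the fits as independent.
    """
    if lapse_south.parameter != lapse_north.parameter:
        raise ValueError("lapse models must describe the same temperature parameter")
    if lapse_south.slope >= 0 or lapse_north.slope >= 0:
        raise ValueError("lapse slopes must be negative")

    a_s, b_s = lapse_south.intercept, lapse_south.slope
    a_n, b_n = lapse_north.intercept, lapse_north.slope
    cov_s, cov_n = lapse_south.coef_covariance, lapse_north.coef_covariance

    offset = a_n - a_s
    se_offset = float(np.sqrt(cov_s[0, 0] + cov_n[0, 0]))

    if parallel:
        b_bar = 0.5 * (b_s + b_n)
        disp = offset / (-b_bar)
        # gradients of disp wrt (a_s, b_s) and (a_n, b_n)
        g_s = np.array([1.0 / b_bar, offset / (2.0 * b_bar**2)])
        g_n = np.array([-1.0 / b_bar, offset / (2.0 * b_bar**2)])
        var = float(g_s @ cov_s @ g_s + g_n @ cov_n @ g_n)
        z_ref = None
    else:
        if reference_elevation is None:
            lo = min(lapse_south.elevation_range[0], lapse_north.elevation_range[0])
            hi = max(lapse_south.elevation_range[1], lapse_north.elevation_range[1])
            reference_elevation = 0.5 * (lo + hi)
        z = reference_elevation
        disp = (a_s + b_s * z - a_n) / b_n - z
        g_s = np.array([1.0 / b_n, z / b_n])
        g_n = np.array([-1.0 / b_n, -(a_s + b_s * z - a_n) / b_n**2])
        var = float(g_s @ cov_s @ g_s + g_n @ cov_n @ g_n)
        z_ref = float(z)

    return DisplacementPrediction(
        parameter=lapse_south.parameter,
        temp_offset=float(offset),
        se_temp_offset=se_offset,
        displacement=float(disp),
        se_displacement=float(np.sqrt(var)),
        parallel=bool(parallel),
        reference_elevation=z_ref,
    )
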