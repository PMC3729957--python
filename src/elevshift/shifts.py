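"""Shift inference: paired regional optima, CI-overlap tests, and
assemblage-level comparison with temperature-predicted displacements.

Per species, the estimated altitudinal shift is the northern minus the
southern density optimum; a shift is declared significant when the two
regions' 84% Fieller intervals fail to overlap on the side of the shift
(south upper < north lower for upslope shifts, and symmetrically for
downslope ones) — the standard approximation of a 5%-level two-sample test.

At the assemblage level, one-sample Wilcoxon signed-rank tests compare the
shifts to zero and to the displacement each temperature parameter predicts
from its fitted lapses; RMSE of a regression of observed on predicted
northern optima ranks the parameters as predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from elevshift.lapse import DisplacementPrediction, LapseModel, translate_elevation
from elevshift.optimum import GaussianFit

#: exact signed-rank enumeration is used up to this n (no ties/zeros), the
#: normal approximation with tie + continuity correction beyond — mirroring
#: R's wilcox.test, the field's reference implementation.
EXACT_WILCOXON_MAX_N = 49

__all__ = [
    "SpeciesShift", "ShiftSummary", "species_shift", "ci_nonoverlap",
    "summarize_shifts", "wilcoxon_signed_rank", "compare_predictions",
    "shift_table", "plot_shifts", "EXACT_WILCOXON_MAX_N",
]


@dataclass(frozen=True)
class SpeciesShift:
    """Paired south/north optima for one species (a Table-2-style row)."""

    species_id: str
    south_optimum: float
    south_ci_low: float
    south_ci_high: float
    north_optimum: float
    north_ci_low: float
    north_ci_high: float
    shift: float               # north - south, metres
    significant: bool
    note: str = ""


@dataclass(frozen=True)
class ShiftSummary:
    n_species: int
    n_positive: int
    n_negative: int
    n_zero: int
    n_significant: int
    n_significant_positive: int
    median_shift: float
    wilcoxon_statistic: float
    wilcoxon_p: float


def _from_gaussian(fit: GaussianFit) -> tuple[float, float, float]:
    lo = fit.ci_low if fit.ci_bounded else np.nan
    hi = fit.ci_high if fit.ci_bounded else np.nan
    return fit.optimum, lo, hi


def species_shift(fit_south: GaussianFit, fit_north: GaussianFit) -> SpeciesShift:
    """Pair two regional fits into a shift record with its significance flag."""
    if fit_south.species_id != fit_north.species_id:
        raise ValueError("fits must describe the same species")
    s_opt, s_lo, s_hi = _from_gaussian(fit_south)
    n_opt, n_lo, n_hi = _from_gaussian(fit_north)
    rec = SpeciesShift(
        species_id=fit_south.species_id,
        south_optimum=s_opt, south_ci_low=s_lo, south_ci_high=s_hi,
        north_optimum=n_opt, north_ci_low=n_lo, north_ci_high=n_hi,
        shift=n_opt - s_opt, significant=False,
    )
    sig, note = _nonoverlap_with_note(rec)
    return SpeciesShift(**{**rec.__dict__, "significant": sig, "note": note})


def _nonoverlap_with_note(rec: SpeciesShift) -> tuple[bool, str]:
    if rec.shift > 0:
        lo, hi = rec.north_ci_low, rec.south_ci_high
    elif rec.shift < 0:
        lo, hi = rec.south_ci_low, rec.north_ci_high
    else:
        return False, ""
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return False, "unbounded CI"
    return bool(hi < lo), ""


def ci_nonoverlap(rec: SpeciesShift) -> bool:
    """Direction-aware 84% CI overlap rule.

    Upslope shift: significant iff the southern upper bound lies below the
    northern lower bound; downslope shift: northern upper below southern
    lower; zero shift never significant.  An unbounded interval on the
    tested side yields False.
    """
    return _nonoverlap_with_note(rec)[0]


def summarize_shifts(records: list[SpeciesShift]) -> ShiftSummary:
    """Counts by sign, sample median, and the Wilcoxon test against zero."""
    if not records:
        raise ValueError("no species shifts to summarize")
    shifts = np.array([r.shift for r in records], dtype=float)
    stat, p, _ = wilcoxon_signed_rank(shifts, 0.0)
    return ShiftSummary(
        n_species=len(records),
        n_positive=int(np.sum(shifts > 0)),
        n_negative=int(np.sum(shifts < 0)),
        n_zero=int(np.sum(shifts == 0)),
        n_significant=int(sum(r.significant for r in records)),
        n_significant_positive=int(sum(r.significant and r.shift > 0 for r in records)),
        median_shift=float(np.median(shifts)),
        wilcoxon_statistic=stat,
        wilcoxon_p=p,
    )


def wilcoxon_signed_rank(values, mu0: float = 0.0) -> tuple[float, float, int]:
    """Two-sided one-sample Wilcoxon signed-rank test of median = ``mu0``.

    Zero differences are dropped (Wilcoxon convention).  The exact null
    distribution is used for n <= 49 without ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns
    ``(statistic, p, n_used)``; if every difference is zero, p = 1.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return (0.0, 1.0, 0)
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and not has_ties) else "approx"
    res = wilcoxon(d, method=method, correction=True)
    return (float(res.statistic), float(res.pvalue), n)


def shift_table(records: list[SpeciesShift]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def plot_shifts(records: list[SpeciesShift], path, *, predicted: float | None = None) -> None:
    """Two-panel figure: paired optima vs the identity line, and the shift
    histogram with its median (and optionally a predicted displacement)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    south = [r.south_optimum for r in records]
    north = [r.north_optimum for r in records]
    shifts = [r.shift for r in records]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    sig = [r.significant for r in records]
    ax1.scatter(south, north, c=["k" if s else "none" for s in sig],
                edgecolors="k", s=25)
    lims = [min(south + north), max(south + north)]
    ax1.plot(lims, lims, "--", color="grey", lw=1)
    ax1.set_xlabel("southern optimum (m)")
    ax1.set_ylabel("northern optimum (m)")
    ax2.hist(shifts, bins=15, color="lightgrey", edgecolor="k")
    ax2.axvline(0, color="grey", lw=1)
    ax2.axvline(float(np.median(shifts)), color="k", lw=1.5, label="median")
    if predicted is not None:
        ax2.axvline(predicted, color="k", ls="--", lw=1, label="predicted")
    ax2.set_xlabel("shift north - south (m)")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_predictions(
    records: list[SpeciesShift],
    lapse_pairs: dict[str, tuple[LapseModel, LapseModel]],
    predictions: dict[str, DisplacementPrediction],
) -> pd.DataFrame:
    """Assemblage-level comparison of observed and predicted shifts.

    For each temperature parameter: a Wilcoxon test of the observed shifts
    against the parameter's single predicted displacement, and the RMSE of
    an OLS regression of observed northern optima on per-species predicted
    northern optima (each species' southern optimum translated along the
    parameter's isotherms).
    """
    obs_shift = np.array([r.shift for r in records], dtype=float)
    obs_north = np.array([r.north_optimum for r in records], dtype=float)
    south_opt = np.array([r.south_optimum for r in records], dtype=float)

    rows = []
    for param, (lapse_s, lapse_n) in lapse_pairs.items():
        pred = predictions[param]
        pred_north = translate_elevation(south_opt, lapse_s, lapse_n)
        if not np.all(np.isfinite(pred_north)) or not np.isfinite(pred.displacement):
            rows.append({
                "parameter": param, "predicted_displacement": pred.displacement,
                "wilcoxon_statistic": np.nan, "wilcoxon_p": np.nan,
                "rmse": np.nan, "n_species": len(records), "flagged": True,
            })
            continue
        stat, p, _ = wilcoxon_signed_rank(obs_shift, pred.displacement)
        X = np.column_stack([np.ones_like(pred_north), pred_north])
        beta, *_ = np.linalg.lstsq(X, obs_north, rcond=None)
        resid = obs_north - X @ beta
        rmse = float(np.sqrt(np.mean(resid**2)))
        rows.append({
            "parameter": param, "predicted_displacement": pred.displacement,
            "wilcoxon_statistic": stat, "wilcoxon_p": p,
            "rmse": rmse, "n_species": len(records), "flagged": False,
        })
    return pd.DataFrame(rows)
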