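"""Packaged reference data."""

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_table2", "table2_shift_records"]


def load_table2() -> pd.DataFrame:
    """Published per-species density optima for the two subregions.

    One row per species with its southern and northern optimum elevations,
    84% Fieller confidence bounds, percent deviance explained, site counts,
    and the printed altitudinal shift (north minus south, metres).
    """
    with resources.files(__package__).joinpath("table2_optima.csv").open() as fh:
        return pd.read_csv(fh)


def table2_shift_records():
    """The published table as :class:`~elevshift.shifts.SpeciesShift` records.

    Significance is recomputed from the printed intervals with the
    direction-aware CI-overlap rule.
    """
    from elevshift.shifts import SpeciesShift, _nonoverlap_with_note

    out = []
    for _, r in load_table2().iterrows():
        rec = SpeciesShift(
            species_id=r["species"],
            south_optimum=r["south_optimum"],
            south_ci_low=r["south_ci_low"],
            south_ci_high=r["south_ci_high"],
            north_optimum=r["north_optimum"],
            north_ci_low=r["north_ci_low"],
            north_ci_high=r["north_ci_high"],
            shift=float(r["north_optimum"] - r["south_optimum"]),
            significant=False,
        )
        sig, note = _nonoverlap_with_note(rec)
        out.append(SpeciesShift(**{**rec.__dict__, "significant": sig, "note": note}))
    return out
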