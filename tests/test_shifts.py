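"""Per-species shifts, CI-overlap significance, Wilcoxon tests, predictions."""

import itertools

import numpy as np
import pytest

from elevshift.data import load_table2, table2_shift_records
from elevshift.lapse import fit_lapse, predict_displacement
from elevshift.optimum import GaussianFit
from elevshift.shifts import (
    SpeciesShift, ci_nonoverlap, compare_predictions, species_shift,
    summarize_shifts, wilcoxon_signed_rank,
)


def _gfit(species, region, optimum, lo, hi, bounded=True):
    """Minimal GaussianFit carrying an optimum and CI (b2<0 so it is valid)."""
    return GaussianFit(
        species_id=species, region=region,
        b0=0.0, b1=2e-5 * optimum, b2=-1e-5,
        coef_covariance=np.zeros((3, 3)),
        optimum=optimum, ci_low=lo, ci_high=hi, ci_level=0.84,
        ci_bounded=bounded, pct_deviance_explained=50.0, n_sites=30,
    )


def _rec(shift, s_lo=0.0, s_hi=0.0, n_lo=0.0, n_hi=0.0):
    return SpeciesShift("x", 0.0, s_lo, s_hi, shift, n_lo, n_hi, shift, False)


class TestSpeciesShift:
    def test_published_shift_examples(self):
        t2 = load_table2().set_index("species")
        dove = t2.loc["Brown Cuckoo-Dove"]
        s = species_shift(
            _gfit("d", "south", dove.south_optimum, dove.south_ci_low, dove.south_ci_high),
            _gfit("d", "north", dove.north_optimum, dove.north_ci_low, dove.north_ci_high),
        )
        assert s.shift == pytest.approx(189.01, abs=1e-9)
        assert s.significant
        pigeon = t2.loc["Topknot Pigeon"]
        s = species_shift(
            _gfit("p", "south", pigeon.south_optimum, pigeon.south_ci_low, pigeon.south_ci_high),
            _gfit("p", "north", pigeon.north_optimum, pigeon.north_ci_low, pigeon.north_ci_high),
        )
        assert s.shift == pytest.approx(-96.69, abs=1e-9)

    def test_identical_fits_zero_not_significant(self):
        f = _gfit("s", "south", 700.0, 650.0, 750.0)
        g = _gfit("s", "north", 700.0, 650.0, 750.0)
        s = species_shift(f, g)
        assert s.shift == 0.0
        assert not s.significant

    def test_mismatched_species_rejected(self):
        with pytest.raises(ValueError):
            species_shift(_gfit("a", "south", 1, 0, 2), _gfit("b", "north", 1, 0, 2))


class TestCINonoverlap:
    def test_published_positive_cases(self):
        recs = {r.species_id: r for r in table2_shift_records()}
        assert ci_nonoverlap(recs["Fernwren"])                      # 857.1 < 893.4
        assert not ci_nonoverlap(recs["Yellow-throated Scrubwren"])  # 828.29 >= 727.65

    def test_identical_intervals_overlap(self):
        assert not ci_nonoverlap(
            SpeciesShift("x", 700, 650, 750, 710, 650, 750, 10.0, False))

    def test_negative_shift_uses_other_sides(self):
        # north entirely below south -> significant downslope shift
        assert ci_nonoverlap(
            SpeciesShift("x", 900, 850, 950, 700, 650, 750, -200.0, False))

    def test_unbounded_interval_never_significant(self):
        assert not ci_nonoverlap(
            SpeciesShift("x", 500, 400, 600, 800, np.nan, np.nan, 300.0, False))


class TestSummaries:
    def test_published_table_summary(self):
        s = summarize_shifts(table2_shift_records())
        assert s.median_shift == pytest.approx(80.66, abs=1e-9)
        assert (s.n_positive, s.n_negative) == (19, 7)
        assert s.n_significant_positive == 10

    def test_sign_counts_and_median(self):
        recs = [_rec(v) for v in (-1.0, 0.0, 1.0)]
        s = summarize_shifts(recs)
        assert (s.n_positive, s.n_negative, s.n_zero) == (1, 1, 1)
        assert s.median_shift == 0.0

    def test_median_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 100, 15)
        a = summarize_shifts([_rec(v) for v in vals])
        b = summarize_shifts([_rec(v) for v in rng.permutation(vals)])
        assert a.median_shift == pytest.approx(b.median_shift)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_shifts([])


def _brute_force_signed_rank_p(d):
    """Independent oracle: enumerate all sign patterns of the ranked |d|."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s])
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_three_values_exact_quarter(self):
        stat, p, n = wilcoxon_signed_rank([1.0, 2.0, 3.0], 0.0)
        assert n == 3
        assert p == pytest.approx(0.25, abs=1e-12)
        assert p == pytest.approx(_brute_force_signed_rank_p([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, 10)
        _, p, _ = wilcoxon_signed_rank(d, 0.0)
        assert p == pytest.approx(_brute_force_signed_rank_p(d), abs=1e-9)

    def test_symmetric_values_near_null(self):
        vals = [10.0, -10.0 + 1e-9, 5.0, -5.0 + 1e-9, 2.0, -2.0 + 1e-9]
        stat, p, n = wilcoxon_signed_rank(vals, 0.0)
        assert p > 0.8

    def test_zeros_dropped(self):
        _, p3, n3 = wilcoxon_signed_rank([1.0, 2.0, 3.0, 0.0, 0.0], 0.0)
        assert n3 == 3
        assert p3 == pytest.approx(0.25, abs=1e-12)

    def test_all_zero_p_one(self):
        stat, p, n = wilcoxon_signed_rank([5.0, 5.0], 5.0)
        assert (p, n) == (1.0, 0)


class TestComparePredictions:
    def _lapses(self, off_n=0.41):
        z = np.linspace(0, 1600, 150)
        s = fit_lapse(z, 24.0 - 0.0051 * z, region="south", parameter="MAT")
        n = fit_lapse(z, 24.0 + off_n - 0.0051 * z, region="north", parameter="MAT")
        return s, n

    def test_perfect_predictions_zero_rmse(self):
        s, n = self._lapses()
        pred = predict_displacement(s, n, parallel=True)
        # observations placed exactly on the predicted displacement
        recs = [SpeciesShift(f"s{i}", 300.0 + 50 * i, 0, 0,
                             300.0 + 50 * i + pred.displacement, 0, 0,
                             pred.displacement, False)
                for i in range(12)]
        out = compare_predictions(recs, {"MAT": (s, n)}, {"MAT": pred})
        row = out.iloc[0]
        assert row["rmse"] == pytest.approx(0.0, abs=1e-6)
        assert not row["flagged"]

    def test_centered_null_large_p(self):
        s, n = self._lapses()
        pred = predict_displacement(s, n, parallel=True)
        d = pred.displacement
        offsets = [-30, -20, -10, -1, 1, 10, 20, 30]
        recs = [SpeciesShift(f"s{i}", 500.0, 0, 0, 500.0 + d + o, 0, 0, d + o, False)
                for i, o in enumerate(offsets)]
        out = compare_predictions(recs, {"MAT": (s, n)}, {"MAT": pred})
        assert out.iloc[0]["wilcoxon_p"] > 0.5
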