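"""Detection functions, effective strip widths and density calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from elevshift.distance import (
    InsufficientDetections, calibrate_density, effective_strip_width,
    fit_detection, pool_sparse, site_densities,
)
from elevshift.synthetic import SpeciesTruth, simulate_surveys


class TestESW:
    def test_perfect_detection_limit(self):
        assert effective_strip_width(50 * 75.0, 75.0) == pytest.approx(75.0, rel=0.01)

    def test_vanishing_sigma_limit(self):
        assert effective_strip_width(1e-6, 75.0) == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("sigma,w", [(30.0, 75.0), (12.0, 75.0), (60.0, 40.0), (100.0, 200.0)])
    def test_matches_quadrature(self, sigma, w):
        oracle = quad(lambda r: np.exp(-r**2 / (2 * sigma**2)), 0, w)[0]
        assert effective_strip_width(sigma, w) == pytest.approx(oracle, abs=1e-8)

    def test_strictly_increasing_in_sigma(self):
        grid = np.linspace(5.0, 300.0, 60)
        esw = [effective_strip_width(s, 75.0) for s in grid]
        assert np.all(np.diff(esw) > 0)

    @settings(derandomize=True, max_examples=50)
    @given(sigma=st.floats(0.5, 500.0), w=st.floats(1.0, 300.0))
    def test_bounded_by_truncation(self, sigma, w):
        esw = effective_strip_width(sigma, w)
        assert 0 < esw <= w

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            effective_strip_width(-1.0, 75.0)
        with pytest.raises(ValueError):
            effective_strip_width(30.0, 0.0)


class TestDetectionFit:
    def test_sigma_recovery_at_n1000(self):
        rng = np.random.default_rng(42)
        sigma, w = 30.0, 75.0
        r = np.abs(rng.normal(0, sigma, 5000))
        r = r[r <= w][:1000]
        fit = fit_detection(r, w)
        assert fit.sigma == pytest.approx(sigma, rel=0.05)
        assert 0 < fit.esw <= w

    def test_insufficient_detections_flagged(self):
        with pytest.raises(InsufficientDetections):
            fit_detection([10.0, 20.0], 75.0)

    def test_rejects_out_of_range_distances(self):
        r = np.linspace(0, 80, 40)
        with pytest.raises(ValueError, match="truncation"):
            fit_detection(r, 75.0)


class TestCalibration:
    def test_zero_count_zero_density(self):
        assert calibrate_density(0.0, 25.0, 150.0) == 0.0

    def test_arithmetic_example(self):
        # 4 birds over 2*25*150 m^2 = 0.75 ha
        assert calibrate_density(4.0, 25.0, 150.0) == pytest.approx(4 / 7500 * 1e4)

    def test_doubling_esw_halves_density(self):
        d1 = calibrate_density(4.0, 25.0, 150.0)
        d2 = calibrate_density(4.0, 50.0, 150.0)
        assert d2 == pytest.approx(d1 / 2)

    @settings(derandomize=True, max_examples=50)
    @given(count=st.floats(0.0, 50.0), esw=st.floats(1.0, 75.0), L=st.floats(10.0, 1000.0))
    def test_calibration_identity(self, count, esw, L):
        d = calibrate_density(count, esw, L)
        assert d * (2 * esw * L / 1e4) == pytest.approx(count, abs=1e-9)

    def test_rejects_zero_area(self):
        with pytest.raises(ValueError):
            calibrate_density(1.0, 0.0, 150.0)


class TestPooling:
    elev = {f"s{i}": 200.0 * i for i in range(5)}

    def test_identity_when_sufficient(self):
        n = {s: 40 for s in self.elev}
        pooling = pool_sparse(n, 30, self.elev)
        assert all(pooling[s] == s for s in self.elev)

    def test_forced_merge_of_adjacent_halves(self):
        elev = {"a": 0.0, "b": 200.0}
        pooling = pool_sparse({"a": 15, "b": 15}, 30, elev)
        assert pooling["a"] == pooling["b"] == "a+b"

    def test_total_below_threshold_excluded(self):
        assert pool_sparse({"a": 5, "b": 5}, 30, {"a": 0.0, "b": 200.0}) is None

    def test_merges_nearest_by_elevation(self):
        elev = {"lo": 0.0, "mid": 100.0, "hi": 1000.0}
        pooling = pool_sparse({"lo": 40, "mid": 10, "hi": 40}, 30, elev)
        assert pooling["mid"] == pooling["lo"]
        assert pooling["hi"] == "hi"

    def test_pooled_esw_close_to_per_site(self):
        """With constant detection sigma, pooling barely changes the ESW of
        well-sampled sites (per-site fits need enough detections for the
        comparison to measure pooling rather than sampling noise)."""
        from elevshift.synthetic import StudyDesign, generate_design
        design = StudyDesign(n_sites_per_region=9, surveys_per_site=60, seed=2)
        sites = generate_design(design)
        sp = SpeciesTruth("g", 19.5, 1.8, 12.0, 30.0)
        surveys = simulate_surveys(design, sites, [sp], seed=2)
        south = surveys[surveys.region == "south"]
        all_d = np.concatenate([np.asarray(d) for d in south["distances"]])
        pooled = fit_detection(all_d, design.truncation_width)
        per_site = []
        for _, g in south.groupby("site_id"):
            d = np.concatenate([np.asarray(x) for x in g["distances"]])
            if d.size >= 300:
                per_site.append(fit_detection(d, design.truncation_width).esw)
        assert per_site, "simulation produced no site with enough detections"
        assert np.all(np.abs(np.array(per_site) - pooled.esw) / pooled.esw < 0.10)


def test_site_densities_recovers_truth(medium_design, medium_sites):
    """Calibrated densities at the optimal site come back within 10% of the
    simulated peak density (sigma within 5% at n >= 1000 detections)."""
    # optimum placed exactly on the 800-m band (south MAT 24 - 0.0051*800)
    sp = SpeciesTruth("g1", 19.92, 1.2, 8.0, 30.0)
    surveys = simulate_surveys(medium_design, medium_sites, [sp], seed=5)
    dens, report, excl = site_densities(
        surveys, truncation=medium_design.truncation_width,
        transect_length=medium_design.transect_length,
    )
    assert excl.empty
    assert (report["n_detections"] >= 30).all()
    # sigma recovery on all pooled distances of the region (n >= 1000)
    all_d = np.concatenate([np.asarray(d) for d in surveys["distances"]])
    assert all_d.size >= 1000
    region_fit = fit_detection(all_d, medium_design.truncation_width)
    assert region_fit.sigma == pytest.approx(30.0, rel=0.05)
    south = dens[dens.region == "south"]
    peak_band = south.loc[south.density.idxmax(), "elevation"]
    band = south[south.elevation == peak_band]
    assert band["density"].mean() == pytest.approx(8.0, rel=0.10)
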