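import numpy as np
import pytest

from elevshift.synthetic import (
    StudyDesign, SpeciesTruth, generate_design, simulate_surveys,
)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_sites_per_region=9, seed=7)


@pytest.fixture(scope="session")
def small_sites(small_design):
    return generate_design(small_design)


@pytest.fixture(scope="session")
def medium_design():
    # replicate transects per 200-m band, as in real survey arrays
    return StudyDesign(n_sites_per_region=36, seed=11)


@pytest.fixture(scope="session")
def medium_sites(medium_design):
    return generate_design(medium_design)


@pytest.fixture(scope="session")
def gaussian_species():
    return SpeciesTruth("g1", thermal_optimum=19.5, thermal_breadth=1.2,
                        peak_density=8.0, detection_sigma=30.0)


@pytest.fixture(scope="session")
def medium_surveys(medium_design, medium_sites, gaussian_species):
    return simulate_surveys(medium_design, medium_sites, [gaussian_species], seed=11)
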