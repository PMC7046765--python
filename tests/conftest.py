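import numpy as np
import pytest

import truescale as ts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def age_prior():
    return ts.AgePrior(T=20.0)


@pytest.fixture(scope="session")
def spheroid_prior():
    # an 11-day-old spheroid from the default growth model; no necrotic
    # core yet since r < d_N
    growth = ts.GrowthModel(intercept=19.2, slope=22.4)
    return ts.SpheroidPrior(r=float(growth.radius(11.0)), d_N=270.0)


@pytest.fixture(scope="session")
def cell_cycle_population(age_prior):
    """10^4 simulated cycling cells with rank-uniform pseudotime."""
    params = ts.CellCycleParams()
    ages = ts.sample_ages(10_000, age_prior, seed=42)
    pop = ts.simulate_cell_cycle_markers(ages, params, seed=43)
    pop.pseudotime = ts.distort_to_pseudotime(ages, "rank_uniform")
    return pop


@pytest.fixture(scope="session")
def spheroid_population(spheroid_prior):
    """10^4 simulated spheroid cells with power-warped pseudotime."""
    depths = ts.sample_depths(10_000, spheroid_prior, seed=7)
    pop = ts.simulate_spheroid_markers(depths, ts.SpheroidParams(), seed=8)
    pop.pseudotime = ts.distort_to_pseudotime(depths, "power")
    return pop
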