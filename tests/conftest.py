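import warnings

import numpy as np
import pytest

from carmap import (ModelSpec, SamplerConfig, expected_counts, run_mcmc,
                    tabulate_counts)
from carmap.simulate import SimulationParams, make_grid_geometry, simulate_dataset
from carmap.table1 import table1_fixture


@pytest.fixture(scope="session")
def table1_records():
    return table1_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """4x4 grid, small effects: a quick but non-trivial dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(SimulationParams(rows=4, cols=4, seed=7))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short 2-chain fit on the 4x4 dataset, reused across tests."""
    sim = small_sim
    E = expected_counts(sim.counts)
    spec = ModelSpec(adjacency=sim.adjacency,
                     covariate_names=sim.covariates.column_names)
    cfg = SamplerConfig(n_chains=2, n_burnin=400, n_iter=1200, thin=3, seed=11)
    samples = run_mcmc(spec, sim.counts, E, sim.covariates, cfg)
    return sim, E, spec, cfg, samples


@pytest.fixture
def grid_zones():
    return make_grid_geometry(3, 3)
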