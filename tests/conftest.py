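import logging

import pytest

from covselpk import simulate as sim

logging.getLogger("covselpk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design():
    return sim.default_design()


@pytest.fixture(scope="session")
def small_dataset():
    """50 subjects, weak covariate effect, no covariate correlation."""
    covs = sim.sample_covariates(sim.default_covariate_specs(), 0.0, 50, seed=101)
    return sim.simulate_dataset(covs, sim.default_design(),
                                sim.default_true_params(0.026), seed=102)


@pytest.fixture(scope="session")
def strong_dataset():
    """80 subjects, strong covariate effect - near-certain selection."""
    covs = sim.sample_covariates(sim.default_covariate_specs(), 0.0, 80, seed=201)
    return sim.simulate_dataset(covs, sim.default_design(),
                                sim.default_true_params(0.045), seed=202)
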