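import numpy as np
import pytest

from knockoffml.sim_data import (
    CovarianceSpec,
    SimulationScenario,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cov():
    """12 features: two triplet groups, four continuous singletons, two
    binary singletons."""
    return CovarianceSpec(
        p=12,
        groups=((0, 1, 2), (3, 4, 5)),
        within_group_rho=0.5,
        background_rho=0.1,
        binary_columns=frozenset({10, 11}),
    )


@pytest.fixture(scope="session")
def small_scenario(small_cov):
    return SimulationScenario(
        trait="dichotomous",
        link="linear",
        n=600,
        cov=small_cov,
        n_risk_groups=2,
        seed=7,
        calibration_n=100_000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)
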