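import numpy as np
import pytest

from ecsurv.simulate import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Moderate cohort under the default stated world (n = 4000, seed 0)."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def planted_config():
    """Four equal planted strata followed administratively to month 60."""
    return GeneratorConfig(
        n_patients=4000,
        group_mix=(0.25, 0.25, 0.25, 0.25),
        censor_admin_range_months=(60.0, 60.0),
        dropout_rate_per_month=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return simulate_cohort(planted_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
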