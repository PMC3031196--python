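import warnings

import pytest

from orassess import AdaptationConfig, build_profile, default_simulation_config, fixture_small, simulate_caselog


@pytest.fixture(scope="session")
def config():
    return AdaptationConfig()


@pytest.fixture(scope="session")
def small_log():
    return fixture_small()


@pytest.fixture(scope="session")
def sim_log():
    """One default simulated facility (seed 7), shared across tests."""
    return simulate_caselog(default_simulation_config(seed=7))


@pytest.fixture(scope="session")
def sim_profile(sim_log):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_profile(sim_log)
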