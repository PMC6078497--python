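import numpy as np
import pytest

from gridperturb.net_core import NetworkConfig, build_weights


@pytest.fixture(scope="session")
def small_config():
    """A reduced aperiodic network used by simulation unit tests."""
    return NetworkConfig.for_topology("aperiodic", N_EL=100, N_ER=100, N_I=40,
                                      seed=0)


@pytest.fixture(scope="session")
def small_weights(small_config):
    return build_weights(small_config)


@pytest.fixture(scope="session")
def default_config():
    return NetworkConfig.for_topology("aperiodic", seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
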