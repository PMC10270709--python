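import numpy as np
import pytest

from sgm.params import LocalCircuitParams, NetworkParams
from sgm.synth import SynthSpec, synth_connectome


@pytest.fixture(scope="session")
def small_conn():
    """12-region synthetic connectome used across network-level tests."""
    return synth_connectome(SynthSpec(N=12, density=0.6, seed=3))


@pytest.fixture(scope="session")
def conn20():
    """Sparser 20-region connectome (wider eigenvalue spread)."""
    return synth_connectome(SynthSpec(N=20, density=0.3, seed=1))


@pytest.fixture
def fig1_stable():
    return LocalCircuitParams(tau_e=0.012, tau_i=0.003, g_ei=0.4, g_ii=0.5)


@pytest.fixture
def default_net():
    return NetworkParams(tau_G=0.015, alpha=0.8, v=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
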