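import numpy as np
import pytest

from gfd.fixtures import core_network_fixture, gas_table_fixture
from gfd.kinetics import build_ensemble, decompose
from gfd.synth import SyntheticConfig, make_reference_state, make_toy_networks


@pytest.fixture(scope="session")
def core():
    return core_network_fixture()


@pytest.fixture(scope="session")
def gas_table():
    return gas_table_fixture()


@pytest.fixture(scope="session")
def toys():
    return make_toy_networks()


@pytest.fixture(scope="session")
def synth_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def reference(core, synth_config):
    return make_reference_state(core, synth_config)


@pytest.fixture(scope="session")
def decomposition(core, reference):
    return decompose(core, reference.v_ref)


@pytest.fixture(scope="session")
def ensemble18(decomposition, reference):
    """18 locally stable members (stability screen only; fast)."""
    ens = build_ensemble(decomposition, reference, (), n_members=18, seed=7, budget=120)
    assert len(ens) == 18
    return ens


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220324)
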