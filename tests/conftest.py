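import numpy as np
import pytest

from spikeloop.neuron import NeuronParams, NeuronState


@pytest.fixture(scope="session")
def msn_params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture()
def down_state() -> NeuronState:
    return NeuronState(v=-80.0, u=0.0, g_exc=0.0, g_inh=0.0, t_ns=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20250917)
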