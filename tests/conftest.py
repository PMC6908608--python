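import numpy as np
import pytest

from repertoire import synth


@pytest.fixture
def chain():
    """Chain model with closed-form optimum 5.0 (yield 0.5 x uptake 10)."""
    return synth.make_chain_model()


@pytest.fixture
def fermenter():
    return synth.make_fermenter_model()


@pytest.fixture
def interaction_pairs():
    return synth.make_interaction_pairs()


@pytest.fixture
def invertase():
    return synth.make_invertase_scenario()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
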