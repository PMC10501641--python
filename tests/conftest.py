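import numpy as np
import pytest

from blockhmm import BlockHMM, TransitionParams, make_reference_agent


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_model() -> BlockHMM:
    return make_reference_agent()


@pytest.fixture(scope="session")
def reference_sample(reference_model):
    """1000 blocks x 30 trials from the three-mode reference mixture."""
    states, Y = reference_model.sample(1000, 30, random_state=1)
    return states, Y


@pytest.fixture
def two_mode_model() -> BlockHMM:
    """Small well-separated two-mode model for exact-inference checks."""
    modes = [TransitionParams(1.0, 2.0, 0.05), TransitionParams(8.0, 0.3, 0.3)]
    transmat = [[0.9, 0.1], [0.2, 0.8]]
    return BlockHMM.from_params(modes, transmat, [0.6, 0.4])
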