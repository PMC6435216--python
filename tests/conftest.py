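import numpy as np
import pytest

from dcmpeb import build_network, default_priors
from dcmpeb.synthetic import random_gain


@pytest.fixture(scope="session")
def chain2():
    return build_network("chain2")


@pytest.fixture(scope="session")
def chain2_prior(chain2):
    return default_priors(chain2)


@pytest.fixture(scope="session")
def gain2():
    return random_gain(2, 2, seed=3)


@pytest.fixture(scope="session")
def freqs():
    """Coarse analysis grid used throughout the small-network tests."""
    return np.arange(4.0, 41.0, 4.0)
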