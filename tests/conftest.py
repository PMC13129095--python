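import numpy as np
import pytest

from predinet import make_network


@pytest.fixture(scope="session")
def small_trained_net():
    """N=600, P=2 network after learning at a moderate gain."""
    return make_network(N=600, P=2, mu=0.9, b=5.0, seed=11)


@pytest.fixture(scope="session")
def small_untrained_net():
    return make_network(N=600, P=2, mu=0.0, b=5.0, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
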