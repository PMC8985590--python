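import numpy as np
import pytest
from hypothesis import settings

from eei import default_community, random_community

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def weak_weak():
    """Symmetric baseline with weak foraging and immune trade-offs."""
    return default_community(zeta=1.0, tau=1.0)


@pytest.fixture
def strong_strong():
    return default_community(zeta=0.01, tau=0.01)


@pytest.fixture
def random_communities(rng):
    return [random_community(rng) for _ in range(20)]
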