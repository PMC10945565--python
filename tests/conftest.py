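import numpy as np
import pytest

from statedyn.simulate import random_covariances


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def spd_covs():
    """Three distinct, well-conditioned 5x5 SPD matrices."""
    return random_covariances(3, 5, np.random.default_rng(7))
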