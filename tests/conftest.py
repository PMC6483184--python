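import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_distributions(rng):
    """A small stack of strictly interior 2-variant usage distributions."""
    return rng.dirichlet((1.0, 1.0), size=4)
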