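import numpy as np
import pytest

from biosigfusion.synthetic_data import SyntheticSpec, gen_two_class_signals


@pytest.fixture(scope="session")
def two_class_segments():
    """A small two-class surrogate dataset shared across tests."""
    return gen_two_class_signals(SyntheticSpec(n_per_class=30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
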