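import numpy as np
import pytest

from fretscope import synthetic
from fretscope.pipeline import preprocess_traces


@pytest.fixture(scope="session")
def yeast_model():
    return synthetic.yeast_ykt6_model()


@pytest.fixture(scope="session")
def rat_model():
    return synthetic.rat_ykt6_model()


@pytest.fixture(scope="session")
def yeast_small_batch(yeast_model):
    """60 traces over a 40 s window: enough statistics for unit tests
    without benchmark-scale runtimes."""
    return synthetic.simulate_batch(yeast_model, 60, 400, seed=11)


@pytest.fixture(scope="session")
def yeast_small_series(yeast_small_batch):
    kept, _ = preprocess_traces([t for t in yeast_small_batch])
    return [t.prebleach_efficiency() for t in kept]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
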