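import numpy as np
import pytest

from seedbank import ModelParams, SampleConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample():
    return SampleConfig(2, 2)


@pytest.fixture
def default_params():
    return ModelParams(c=1.0, K=1.0)
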