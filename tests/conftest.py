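import numpy as np
import pytest

from twistspacer.torsion import DEFAULT_PARAMS, TwistParameters


@pytest.fixture
def params() -> TwistParameters:
    return DEFAULT_PARAMS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
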