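import numpy as np
import pytest

from pmwave.bases import ScalingFunctionSpec


@pytest.fixture(scope="session")
def daub_spec():
    return ScalingFunctionSpec("daub_autocorr", M=3)


@pytest.fixture(scope="session")
def shannon_spec():
    return ScalingFunctionSpec("shannon")


@pytest.fixture(scope="session")
def gabor_spec():
    return ScalingFunctionSpec("shannon_gabor", sigma=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
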