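import numpy as np
import pytest
from hypothesis import settings

from cpgwalk.body import default_body
from cpgwalk.muscle import default_muscles

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def body():
    return default_body()


@pytest.fixture(scope="session")
def muscles():
    return default_muscles()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
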