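import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromoband import datasets

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def region_map():
    return datasets.load_region_map()


@pytest.fixture(scope="session")
def interbands():
    return datasets.load_interbands()


@pytest.fixture(scope="session")
def bands():
    return datasets.load_bands()


@pytest.fixture(scope="session")
def region():
    return datasets.region_extent()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
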