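import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsdc import binarize, table1_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture()
def table1_task(table1):
    return binarize(table1)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20160120)
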