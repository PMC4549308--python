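import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vitdmr.instruments import harmonize, load_fixture
from vitdmr.mr_core import wald_ratio

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_records():
    """The packaged four-SNP vitamin D / MS instrument table."""
    return load_fixture()


@pytest.fixture(scope="session")
def wald_estimates(table1_records):
    return [wald_ratio(harmonize(r)) for r in table1_records]


@pytest.fixture()
def rng():
    return np.random.default_rng(20210901)
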