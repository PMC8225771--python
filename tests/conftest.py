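import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from trflp.configio import DEFAULT_ENZYMES, DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER


@pytest.fixture(scope="session")
def alu():
    return DEFAULT_ENZYMES["AluI"]


@pytest.fixture(scope="session")
def hpy():
    return DEFAULT_ENZYMES["Hpy188III"]


@pytest.fixture(scope="session")
def fwd_primer():
    return DEFAULT_FWD_PRIMER


@pytest.fixture(scope="session")
def rev_primer():
    return DEFAULT_REV_PRIMER
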