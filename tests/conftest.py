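import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reader():
    from mdrekit import ReaderContext

    return ReaderContext.dam_gatc()


@pytest.fixture(scope="session")
def mtase_pool():
    from mdrekit import load_mtase_pool

    return load_mtase_pool()


@pytest.fixture(scope="session")
def enzymes():
    from mdrekit import load_enzymes

    return load_enzymes()


@pytest.fixture(scope="session")
def duplexes():
    from mdrekit import gen_oligo_set

    return gen_oligo_set()
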