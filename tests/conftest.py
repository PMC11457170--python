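import pytest
from hypothesis import HealthCheck, settings

from marshcarbon import default_schedule, table1_fixture

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sites():
    """Packaged six-site monitoring table, keyed by site_id."""
    return {s.site_id: s for s in table1_fixture()}


@pytest.fixture(scope="session")
def schedule3():
    """Packaged 3% social-cost-of-methane schedule, 2021-2050."""
    return default_schedule(3.0)
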