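import pytest
from hypothesis import HealthCheck, settings

from minddiet import cohort, scoring

settings.register_profile(
    "ci", deadline=None, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mymindd():
    return scoring.load_scoring_table("MY-MINDD")


@pytest.fixture(scope="session")
def mind_original():
    return scoring.load_scoring_table("MIND-original")


@pytest.fixture(scope="session")
def default_cfg():
    return cohort.default_config()


@pytest.fixture(scope="session")
def cohort_810(default_cfg):
    """One default-config cohort, shared read-only across tests."""
    return cohort.generate_cohort(default_cfg, seed=42)


@pytest.fixture(scope="session")
def cohort_20k(default_cfg):
    """A large cohort for recovery/calibration checks (generated once)."""
    return cohort.generate_cohort(default_cfg, seed=7, n=20_000)
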