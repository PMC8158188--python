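import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def codes():
    from dislokit import CodeSet

    return CodeSet()


@pytest.fixture(scope="session")
def small_profile():
    """A ~1/20-scale patient-level profile for fast end-to-end tests."""
    from dislokit import default_profile, scaled_profile

    return scaled_profile(default_profile(), 0.05)
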