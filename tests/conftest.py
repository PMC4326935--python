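import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirlifespan import LifespanStudy  # noqa: E402


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration simulated study, fitted once per session."""
    study = LifespanStudy.from_simulation()
    results = study.fit()
    return study, results
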