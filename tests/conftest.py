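import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from barcodegap.fixtures import synthetic_checklists  # noqa: E402


@pytest.fixture(scope="session")
def regional():
    """The three synthetic regional checklists (West Siberia / Fennoscandia / Canada and Alaska)."""
    return synthetic_checklists()
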