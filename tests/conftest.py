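from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

REPO_ROOT = Path(__file__).resolve().parents[1]
DEMO_CONFIG = REPO_ROOT / "configs" / "demo.yaml"


@pytest.fixture(scope="session")
def demo_config() -> dict:
    from volconsist.config import load_config

    return load_config(DEMO_CONFIG)


@pytest.fixture(scope="session")
def demo_cohort(demo_config):
    """The demo two-region cohort (n = 20,000), shared across tests."""
    from volconsist.cohort import generate_cohort
    from volconsist.config import cohort_spec_from_config

    spec = cohort_spec_from_config(demo_config)
    return spec, generate_cohort(spec)
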