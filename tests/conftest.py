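import pytest
from hypothesis import HealthCheck, settings

from clonelineage import make_preset30
from clonelineage.pipeline import PipelineConfig, run_reproduce_preset30

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset():
    return make_preset30()


@pytest.fixture(scope="session")
def preset_report():
    """One full end-to-end run on the 30-locus preset, shared by tests."""
    config = PipelineConfig(seed=1)
    config.genealogy.reps = 300
    return run_reproduce_preset30(config)
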