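import pytest
from hypothesis import HealthCheck, settings

import tfacea as t

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_inputs() -> t.StratifiedInputs:
    """Two-stratum fixture with constant mortality and no IHD."""
    return t.generate_worked_toy()


@pytest.fixture(scope="session")
def synth_inputs() -> t.StratifiedInputs:
    """Default 30-strata synthetic input set."""
    return t.generate_inputs(t.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def scenario() -> t.Scenario:
    return t.Scenario()


@pytest.fixture(scope="session")
def central_results(synth_inputs, scenario) -> t.ResultsSummary:
    return t.run_pipeline(synth_inputs, scenario)
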