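import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from prokrates import ObservationNoiseModel, experiment2_scenario
from prokrates.pipeline import RunConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scenario():
    """Default CO2 x warming scenario: (design, truths, chemistry)."""
    return experiment2_scenario()


@pytest.fixture(scope="session")
def noise():
    return ObservationNoiseModel()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture()
def noiseless_truths(scenario):
    """Scenario truths with degenerate cell-volume scatter."""
    _, truths, _ = scenario
    return [dataclasses.replace(t, cv_cell_volume=0.0) for t in truths]
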