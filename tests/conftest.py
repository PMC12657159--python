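import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ketsim import (
    CardioParameters,
    CoPDParameters,
    DoseEvent,
    DoseRegimen,
    MapPDParameters,
    PKParameters,
    Scenario,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pk_params() -> PKParameters:
    return PKParameters()


@pytest.fixture(scope="session")
def cardio_params() -> CardioParameters:
    return CardioParameters()


@pytest.fixture()
def bolus_17p5() -> DoseRegimen:
    """0.25 mg/kg for a 70-kg adult over 1 min."""
    return DoseRegimen([DoseEvent(0.0, 1.0, 17.5)])


@pytest.fixture()
def fast_scenario(bolus_17p5) -> Scenario:
    """Single-bolus scenario at a coarse (but stable) time step."""
    return Scenario(regimen=bolus_17p5, t_end=30.0, dt=0.01)
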