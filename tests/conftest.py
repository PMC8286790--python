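import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sprquant.geometry import ParticleModel
from sprquant.optics import SensorStack
from sprquant.quantify import DetectionSpot, MassConversionConstant


@pytest.fixture(scope="session")
def default_stack() -> SensorStack:
    return SensorStack.default()


@pytest.fixture(scope="session")
def bcg_particle() -> ParticleModel:
    return ParticleModel.bcg_default()


@pytest.fixture(scope="session")
def spot() -> DetectionSpot:
    return DetectionSpot()


@pytest.fixture(scope="session")
def mass_k() -> MassConversionConstant:
    return MassConversionConstant()


@pytest.fixture(scope="session")
def max_monolayer_deg(default_stack, bcg_particle) -> float:
    """Full-monolayer response of the default stack, computed once."""
    from sprquant.optics import max_monolayer_response

    return max_monolayer_response(default_stack, bcg_particle)
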