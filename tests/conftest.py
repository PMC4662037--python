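import pytest

from mtmkit import (
    CheckpointRequirements,
    GeometryParams,
    PhysicalParams,
    default_mea_design,
)
from mtmkit.spikes import StimulusProtocol


@pytest.fixture
def phys():
    return PhysicalParams()


@pytest.fixture
def geom():
    return GeometryParams()


@pytest.fixture
def reqs():
    return CheckpointRequirements()


@pytest.fixture
def design():
    return default_mea_design()


@pytest.fixture
def protocol20():
    """Single train of 20 stimuli at 1.5 Hz."""
    return StimulusProtocol.single_train(20)
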