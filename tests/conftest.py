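import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pseudophase import EmulsionComposition


@pytest.fixture
def anchor_composition() -> EmulsionComposition:
    """1:9 v/v emulsion at the lowest surfactant level of the reference design."""
    return EmulsionComposition(phi_O=0.1, phi_I=0.005, phi_W=0.895)


def make_composition(phi_I: float, phi_O: float = 0.1) -> EmulsionComposition:
    return EmulsionComposition(phi_O=phi_O, phi_I=phi_I, phi_W=1.0 - phi_O - phi_I)
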