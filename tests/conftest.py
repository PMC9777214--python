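import numpy as np
import pytest

from armkin import ArmGeometry


@pytest.fixture
def geometry() -> ArmGeometry:
    """Plausible adult arm geometry (mm)."""
    return ArmGeometry(l2=180.0, d5=300.0, l6=260.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
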