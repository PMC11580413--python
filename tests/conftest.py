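import numpy as np
import pytest

from afm_softscan import (
    HeightField,
    Material,
    TipGeometry,
    make_hemisphere,
    tip_profile,
)


@pytest.fixture(scope="session")
def material():
    """Sample material used throughout: E = 100 MPa, nu = 0.3."""
    return Material(E=100.0, nu=0.3)


@pytest.fixture(scope="session")
def tip_r1():
    """Reference probe: cap radius 1 nm, cone half-angle 20 degrees."""
    return TipGeometry.from_degrees(1.0, 20.0)


@pytest.fixture(scope="session")
def hemisphere5():
    """Elastic hemisphere of radius 5 nm on a 0.1 nm grid."""
    return make_hemisphere(5.0, spacing=0.1)


def brute_force_dilation(tip: TipGeometry, sample: HeightField, position) -> float:
    """Exhaustive first-contact oracle: maximize over ALL cells, no pruning."""
    px, py = position
    d = np.sqrt((sample.x[:, None] - px) ** 2 + (sample.y[None, :] - py) ** 2)
    return max(float((sample.heights - tip_profile(tip, d)).max()), 0.0)


@pytest.fixture(scope="session")
def dilation_oracle():
    return brute_force_dilation
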