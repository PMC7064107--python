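import numpy as np
import pytest

from laxm.phantoms import (
    Ellipsoid,
    PhantomSpec,
    PhantomVolume,
    generate_phantom,
)
from laxm.projection import ScanGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Small phantom spec with the default category counts."""
    return PhantomSpec(grid_size=64, seed=7)


@pytest.fixture
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture
def small_geometry():
    return ScanGeometry(detector_size=64)


@pytest.fixture
def sphere_phantom():
    """One centred sphere, no background: every slice is a disk."""
    spec = PhantomSpec(
        grid_size=32,
        counts={"outer": 0, "chloroplast": 0, "lipid": 0, "gold": 0},
        background_intensity=0.0,
        seed=0,
    )
    sphere = Ellipsoid(
        center=np.zeros(3), semi_axes=np.full(3, 10.0),
        rotation=np.zeros(3), intensity=0.01, category="outer",
    )
    return PhantomVolume(ellipsoids=(sphere,), spec=spec)
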