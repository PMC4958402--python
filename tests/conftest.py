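import numpy as np
import pytest

from navbus.image import SectorGeometry
from navbus.simulator import build_phantom, render_ct


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def default_ct(default_phantom):
    """The default-resolution CT volume, rendered once per test session."""
    return render_ct(default_phantom)


@pytest.fixture(scope="session")
def coarse_geometry():
    """A lower-resolution sector used where rendering speed matters."""
    return SectorGeometry(pixel_spacing_mm=0.4)
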