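import numpy as np
import pytest

from raman3d.cube import HyperspectralCube
from raman3d.phantom import PhantomSpec, SpectralComponent


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A 4×4×8 cube of distinct values with a strictly increasing axis."""
    data = rng.permutation(np.arange(4 * 4 * 8, dtype=np.float64)).reshape(4, 4, 8)
    wn = np.linspace(600.0, 1800.0, 8)
    return HyperspectralCube(data=data, wavenumbers=wn, pixel_size=1.0,
                             integration_time=0.5, provenance="test")


@pytest.fixture
def tiny_phantom_spec():
    """A fast-to-render phantom: 16×16 px, 32 bands, one cell."""
    return PhantomSpec(
        height=16, width=16, n_bands=32, wn_start=500.0, wn_end=1800.0,
        n_cells=1, cell_radius_range=(3.0, 5.0), seed=7,
    )


@pytest.fixture
def gaussian_component():
    return SpectralComponent(
        "test", peaks=[(1450.0, 40.0, 1.0)], lineshape="gaussian",
    )
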