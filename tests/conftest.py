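import numpy as np
import pytest

from padftex import DetectorGeometry, HexLattice2D, PolarGrid


@pytest.fixture
def geom():
    return DetectorGeometry(
        wavelength=0.6702,
        distance=0.694,
        pixel_size=75.0,
        beam_centre=(128.0, 128.0),
        image_shape=(256, 256),
    )


@pytest.fixture
def lattice():
    return HexLattice2D(a=5.0)


@pytest.fixture
def ring_lattice():
    """Single-ring lattice: only the (10) reflections."""
    return HexLattice2D(a=5.0, intensities={"10": 1.0})


@pytest.fixture
def grid(lattice):
    return PolarGrid(q_values=np.linspace(0.5, 3.2, 24), n_phi=360)


@pytest.fixture
def ring_grid(ring_lattice):
    return PolarGrid(q_values=np.array([ring_lattice.q10]), n_phi=360)


@pytest.fixture
def small_grid():
    return PolarGrid(q_values=np.linspace(1.0, 2.0, 8), n_phi=16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
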