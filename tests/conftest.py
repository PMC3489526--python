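import numpy as np
import pytest

from msipipe import Datacube, MzAxis
from msipipe import synthgen


@pytest.fixture
def small_axis():
    return MzAxis(np.arange(500.0, 520.0 + 0.125, 0.25))


@pytest.fixture
def tiny_cube(small_axis):
    """2x2 grid with one absent pixel; distinct spectra per pixel."""
    rng = np.random.default_rng(7)
    coords = np.array([[1, 1], [2, 1], [1, 2]])
    inten = rng.random((3, len(small_axis))) + 0.1
    return Datacube(coords=coords, intensities=inten, axis=small_axis,
                    meta={"acquisition_mode": "profile"})


@pytest.fixture
def clean_two_region():
    """Noise-free two-region cube: ground truth exactly recoverable."""
    spec = synthgen.two_region_spec(20, 20, noise_cv=0.0, seed=0)
    return synthgen.generate_datacube(spec)


@pytest.fixture
def noisy_two_region():
    """Two-region cube at the standard multiplicative noise level CV 0.3."""
    spec = synthgen.two_region_spec(30, 30, noise_cv=0.3, seed=1)
    return synthgen.generate_datacube(spec)
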