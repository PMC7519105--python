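import numpy as np
import pytest

from tactsurf.roughness import roughness_summary
from tactsurf.surface import SpectrumSpec, Surface, generate_sample_matrix


@pytest.fixture(scope="session")
def small_spec() -> SpectrumSpec:
    """Reduced grid for fast tests; the spectral band is unchanged."""
    return SpectrumSpec(grid_n=256)


@pytest.fixture(scope="session")
def samples_small(small_spec):
    return generate_sample_matrix(seeds=(11, 22, 33), spec=small_spec)


@pytest.fixture(scope="session")
def summary_small(samples_small):
    return roughness_summary(samples_small)


@pytest.fixture(scope="session")
def default_spec() -> SpectrumSpec:
    return SpectrumSpec()


@pytest.fixture(scope="session")
def samples_default(default_spec):
    """The full-resolution 3x3 sample matrix (1024^2 heightmaps)."""
    return generate_sample_matrix(seeds=(11, 22, 33), spec=default_spec)


@pytest.fixture(scope="session")
def summary_default(samples_default):
    return roughness_summary(samples_default)


def make_sinusoid(n=256, size=50.0, amplitude=0.3, wavelength=6.25, axis=0) -> Surface:
    """Single-wave heightmap along one axis; wavelength divides the size."""
    pitch = size / n
    x = np.arange(n) * pitch
    wave = amplitude * np.sin(2 * np.pi * x / wavelength)
    h = wave[:, None] * np.ones((1, n)) if axis == 0 else np.ones((n, 1)) * wave[None, :]
    return Surface(heights=h, pitch=pitch, label=("sin", 0.5))
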