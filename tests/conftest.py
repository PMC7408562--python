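import numpy as np
import pytest

from tmzbind import Spectrum


@pytest.fixture
def emission_grid():
    return np.arange(290.0, 400.0 + 0.5, 0.5)


@pytest.fixture
def gaussian_emission(emission_grid):
    """Trp-like Gaussian emission band, peak 334 nm, sigma 15 nm."""
    vals = 1000.0 * np.exp(-0.5 * ((emission_grid - 334.0) / 15.0) ** 2)
    return Spectrum(emission_grid, vals, kind="emission", label="donor")
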