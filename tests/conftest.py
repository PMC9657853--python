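import numpy as np
import pytest

from spectroleaf.hsi_io import MeanSpectrum, SpectralCube, WavelengthGrid
from spectroleaf.synthetic_data import SyntheticConfig


@pytest.fixture
def small_grid():
    return WavelengthGrid.linspace(400.0, 900.0, 51)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_cube(small_grid, rng):
    refl = rng.uniform(0.05, 0.9, size=(8, 8, small_grid.n_bands)).astype(np.float32)
    mask = np.zeros((8, 8), dtype=bool)
    mask.flat[rng.choice(64, size=13, replace=False)] = True
    return SpectralCube(reflectance=refl, grid=small_grid, roi_mask=mask)


@pytest.fixture
def ramp_spectrum(small_grid):
    return MeanSpectrum(values=np.arange(small_grid.n_bands, dtype=float), grid=small_grid)


@pytest.fixture(scope="session")
def tub_config():
    return SyntheticConfig.tub_default(seed=11)


@pytest.fixture(scope="session")
def nft_config():
    return SyntheticConfig.nft_default(seed=11)


@pytest.fixture(scope="session")
def tub_study(tub_config):
    from spectroleaf.synthetic_data import generate_study

    return generate_study(tub_config)
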