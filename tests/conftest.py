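import numpy as np
import pytest

from selsmm import (ImageCube, SimulationConfig, SpectralLibrary,
                    make_endmember_spectra, simulate_scene)


@pytest.fixture(scope="session")
def tm6_library() -> SpectralLibrary:
    """The default four-endmember watershed library on the 6-band profile."""
    return make_endmember_spectra(
        "tm6", ["vegetation", "soil", "soil", "other"], seed=1)


@pytest.fixture(scope="session")
def default_scene():
    """The study-conditions scene: 64x64, 4 endmembers, support <= 2,
    SNR 30 dB."""
    return simulate_scene(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_scene():
    return simulate_scene(SimulationConfig(seed=7, snr_db=np.inf))


@pytest.fixture()
def small_cube() -> ImageCube:
    """A tiny deterministic 3x4 cube with 4 bands and one masked pixel."""
    rng = np.random.default_rng(11)
    data = rng.uniform(0.05, 0.6, size=(3, 4, 4))
    mask = np.zeros((3, 4), dtype=bool)
    mask[1, 2] = True
    return ImageCube(data=data, mask=mask,
                     band_names=["b1", "b2", "b3", "b4"],
                     geotransform=(100.0, 30.0, 0.0, 500.0, 0.0, -30.0))


def planted_simplex_scene(rows=24, cols=24, seed=5):
    """Noiseless scene of strictly interior convex mixtures of 3 affinely
    independent spectra, with one planted pure pixel per endmember."""
    spectra = np.array([
        [0.05, 0.08, 0.05, 0.45, 0.23, 0.12],
        [0.10, 0.15, 0.20, 0.26, 0.33, 0.36],
        [0.20, 0.21, 0.22, 0.21, 0.23, 0.22],
    ])
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(3), size=rows * cols)
    w = 0.06 + 0.82 * w          # strictly interior: every weight < 0.9
    w /= w.sum(axis=1, keepdims=True)
    data = (w @ spectra).reshape(rows, cols, 6)
    pure = [(2, 3), (10, 17), (20, 8)]
    for k, (r, c) in enumerate(pure):
        data[r, c] = spectra[k]
    cube = ImageCube(data=data)
    return cube, spectra, pure
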