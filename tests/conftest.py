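import numpy as np
import pytest

from beechoice import DEFAULT_GRID, ReceptorSet, Spectrum, standard_illuminant_d65


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def receptors(grid):
    return ReceptorSet.honeybee(grid)


@pytest.fixture(scope="session")
def d65(grid):
    return standard_illuminant_d65(grid)


@pytest.fixture()
def flat_background(grid):
    return Spectrum(grid, np.full(len(grid), 0.3), kind="reflectance", name="bg")


def smooth_random_reflectance(grid, rng, name="stim"):
    """A random strictly positive smooth reflectance: sum of broad Gaussians."""
    wl = grid.wavelengths()
    values = np.full(len(wl), 0.05 + 0.1 * rng.random())
    for _ in range(3):
        center = rng.uniform(320, 680)
        sigma = rng.uniform(30, 80)
        amp = rng.uniform(0.05, 0.3)
        values = values + amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return Spectrum(grid, np.clip(values, 0, 1.1), kind="reflectance", name=name)
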