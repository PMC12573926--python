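import numpy as np
import pytest

from ssxdamage.core import UnitCell
from ssxdamage.merging import mc_merge
from ssxdamage.synth import GenerationRecipe, make_toy_structure, simulate_image_set


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure(2.45, 2.1, 0.3, seed=1)


@pytest.fixture(scope="session")
def toy_structure_diatomic():
    return make_toy_structure(2.45, 2.1, 0.3, o_o=1.7, seed=1)


@pytest.fixture(scope="session")
def noiseless_images(toy_structure):
    recipe = GenerationRecipe(
        n_images=20, reflections_per_image=0.6, seed=2, resolution_limit=2.0
    )
    return simulate_image_set(toy_structure, recipe)


@pytest.fixture(scope="session")
def noiseless_merged(noiseless_images):
    return mc_merge(noiseless_images)


@pytest.fixture(scope="session")
def noisy_images(toy_structure):
    recipe = GenerationRecipe(
        n_images=40, reflections_per_image=0.5, noise_sd=0.1, scale_sd=0.15,
        seed=3, resolution_limit=2.0,
    )
    return simulate_image_set(toy_structure, recipe)


@pytest.fixture(scope="session")
def noisy_merged(noisy_images):
    return mc_merge(noisy_images)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def simple_cell():
    return UnitCell(10.0, 10.0, 10.0)
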