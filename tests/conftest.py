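import numpy as np
import pytest

from repbench import (GeneratorConfig, make_latent_representation,
                      make_stimulus_set, simulate_trials)
from repbench.kernel import KernelGrid

# desk-scale task: keeps the 7-category nesting of the full design at a size
# where repeated kernel analyses stay fast
SMALL = GeneratorConfig(n_categories=7, n_objects_per_category=2,
                        n_images_per_object=10, latent_dims=20,
                        n_sites=30, n_trials=12, seed=7)

SMALL_GRID = KernelGrid(n_sigmas=10, n_lambdas=16)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_grid():
    return SMALL_GRID


@pytest.fixture(scope="session")
def stimuli(small_config):
    return make_stimulus_set(small_config)


@pytest.fixture(scope="session")
def latent(stimuli, small_config):
    return make_latent_representation(stimuli, small_config)


@pytest.fixture(scope="session")
def tensor(latent, small_config):
    return simulate_trials(latent, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
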