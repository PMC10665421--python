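import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fractrial import PipelineConfig, generate_population
from fractrial._rng import stream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def small_config():
    return PipelineConfig(seed=7, n_avatars=12)


@pytest.fixture
def small_population(small_config):
    return generate_population(
        small_config.population, small_config.n_avatars, rng=stream(7, "population")
    )


def random_symmetric_tensors(rng, n, scale=1e-3):
    """Random symmetric 3x3 strain tensors with entries of typical strain size."""
    a = rng.normal(0.0, scale, size=(n, 3, 3))
    return 0.5 * (a + np.swapaxes(a, 1, 2))
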