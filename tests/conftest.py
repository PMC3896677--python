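import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_psd(rng: np.random.Generator, p: int, ridge: float = 0.0) -> np.ndarray:
    """Random PSD quadratic form (Gram matrix of a random design)."""
    A = rng.normal(size=(2 * p, p))
    return A.T @ A + ridge * np.eye(p)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_markov_world():
    """A 10-gene benchmark network with noise-free and noisy series."""
    import embryogrn as eg

    net = eg.generate_random_network(seed=3)
    clean = eg.generate_observation_set(net, n_obs=6, noise=eg.NoiseSpec(0, 0), seed=1)
    noisy = eg.generate_observation_set(net, n_obs=4, seed=2)
    return net, clean, noisy
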