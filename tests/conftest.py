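import numpy as np
import pytest

from adaplex import DuplexState, ModelParams


def small_params(n=4, alpha=-0.28 * np.pi, beta=0.6 * np.pi, sigma=0.3,
                 omega1=None, **kwargs) -> ModelParams:
    if omega1 is None:
        omega1 = np.zeros(n)
    adj = np.ones((n, n)) - np.eye(n)
    defaults = dict(n=n, omega1=omega1, omega2=0.0, alpha=alpha, beta=beta,
                    eps1=0.03, eps2=0.3, sigma=sigma, adjacency=adj)
    defaults.update(kwargs)
    return ModelParams(**defaults)


def random_small_state(n=4, seed=0) -> DuplexState:
    rng = np.random.default_rng(seed)
    k1 = rng.uniform(-1, 1, (n, n))
    k2 = rng.uniform(-1, 1, (n, n))
    np.fill_diagonal(k1, 0.0)
    np.fill_diagonal(k2, 0.0)
    return DuplexState(
        rng.uniform(0, 2 * np.pi, n), rng.uniform(0, 2 * np.pi, n), k1, k2
    )


@pytest.fixture
def params4() -> ModelParams:
    return small_params(n=4)


@pytest.fixture
def state4() -> DuplexState:
    return random_small_state(n=4, seed=1)
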