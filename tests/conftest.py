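import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def classes():
    from cnvmix.signal_model import default_classes

    return default_classes()


@pytest.fixture
def prior_cfg():
    from cnvmix.rjmcmc import PriorConfig

    return PriorConfig()


def dense_precision(graph, h):
    """I + hQ for oracle checks on small graphs."""
    return np.eye(graph.n) + h * graph.laplacian()


@pytest.fixture
def small_state():
    """A hand-sized two-component mixture state on 8 SNPs."""
    from cnvmix.rjmcmc import MixtureState, PriorConfig

    cfg = PriorConfig()
    n, kmax = 8, cfg.k_max
    rng = np.random.default_rng(5)
    active = np.zeros(kmax, dtype=bool)
    active[[2, 3]] = True  # diploid and CN=3
    mu = np.zeros(kmax)
    mu[2], mu[3] = 0.01, 0.3
    sigma2 = np.ones(kmax)
    sigma2[2] = sigma2[3] = 0.02
    x = np.zeros((n, kmax))
    x[:, [2, 3]] = rng.normal(size=(n, 2))
    z = np.array([2, 2, 2, 3, 3, 3, 2, 2], dtype=np.int64)
    state = MixtureState(active=active, mu=mu, sigma2=sigma2, x=x, z=z, h=1.5)
    y = np.array([0.0, 0.05, -0.02, 0.31, 0.36, 0.25, 0.01, -0.04])
    return state, y, cfg
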