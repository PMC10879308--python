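import numpy as np
import pytest

import repomet


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world shared by unit tests (fast to fit)."""
    return repomet.generate_world(M=20, N=30, latent_dim=4, density=0.1, noise=0.0, seed=3)


@pytest.fixture(scope="session")
def default_world():
    """The default study-condition world (60 drugs x 80 diseases)."""
    return repomet.generate_world()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def fast_config(completion_epochs=60, metric_epochs=40, k=16, L=2, n=32):
    """Reduced-size configuration for unit tests of the training loops."""
    cfg = repomet.load_config(None)
    cfg.completion.epochs = completion_epochs
    cfg.completion.k = k
    cfg.completion.L = L
    cfg.metric.epochs = metric_epochs
    cfg.metric.n = n
    return cfg
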