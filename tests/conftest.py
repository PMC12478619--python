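import numpy as np
import pytest

from ordmrf.model import ModelParams, gibbs_simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_params(rng, m):
    """Random ragged thresholds (first entry 0) and symmetric interactions."""
    m = np.asarray(m)
    p = m.size
    thresholds = [
        np.concatenate([[0.0], rng.normal(0.0, 1.0, size=mi - 1)]) for mi in m
    ]
    a = rng.normal(0.0, 0.5, size=(p, p))
    sigma = np.triu(a, 1)
    sigma = sigma + sigma.T
    return ModelParams(thresholds, sigma)


@pytest.fixture()
def params_factory():
    return random_params


@pytest.fixture()
def small_data(rng):
    """n=40, p=3, m=3 dataset simulated from a moderate random model."""
    params = random_params(np.random.default_rng(7), [3, 3, 3])
    return gibbs_simulate(params, 40, sweeps=50, seed=11)


def two_var_params(sigma=0.35, mu1=(0.0, 0.3), mu2=(0.0, -0.2)):
    return ModelParams(
        [np.asarray(mu1, dtype=float), np.asarray(mu2, dtype=float)],
        np.array([[0.0, sigma], [sigma, 0.0]]),
    )


@pytest.fixture()
def toy_edge_data():
    """The shared p=2, m=2 single-edge fixture: truth and n=60 dataset."""
    true = two_var_params()
    data = gibbs_simulate(true, 60, sweeps=100, seed=10)
    return true, data


def chain_recovery_truth():
    """Sparse 6-node chain truth for parameter-recovery checks (m=3)."""
    p = 6
    thresholds = [np.array([0.0, -0.5, -1.0]) for _ in range(p)]
    sigma = np.zeros((p, p))
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
    for idx, (i, j) in enumerate(edges):
        w = 0.5 if idx % 2 == 0 else -0.5
        sigma[i, j] = sigma[j, i] = w
    return ModelParams(thresholds, sigma), edges
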