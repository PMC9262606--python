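import numpy as np
import pytest

from drsc.types import ExpressionMatrix, ModelParams


def random_params(rng, p, q, K, beta=0.0):
    """A random valid parameter set (SPD class covariances, positive noise)."""
    W = rng.standard_normal((p, q))
    lam = rng.uniform(0.5, 2.0, size=p)
    mu = rng.standard_normal((K, q)) * 2.0
    Sigma = np.empty((K, q, q))
    for k in range(K):
        A = rng.standard_normal((q, q))
        Sigma[k] = A @ A.T + q * np.eye(q)
    return ModelParams(W, lam, mu, Sigma, beta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def params_factory():
    return random_params


@pytest.fixture
def small_mixture_data():
    """Three well-separated Gaussian clusters in a 2-D latent space, lifted
    to p=12 genes; non-spatial."""
    rng = np.random.default_rng(7)
    n, p, q, K = 150, 12, 2, 3
    mu = np.array([[4.0, 0.0], [-4.0, 3.0], [0.0, -4.0]])
    y = rng.integers(0, K, size=n)
    z = mu[y] + rng.standard_normal((n, q))
    W = np.linalg.qr(rng.standard_normal((p, q)))[0]
    X = z @ W.T + rng.standard_normal((n, p))
    X -= X.mean(axis=0, keepdims=True)
    return ExpressionMatrix(X), y + 1, z
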