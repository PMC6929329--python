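"""Shared fixtures: tiny random problem instances built programmatically."""

import numpy as np
import pytest

from iscluster import Decomposition, Dimensions, ViewSet


def random_orthonormal(rng, p, d):
    """p x d matrix with orthonormal columns, deterministic given rng state."""
    Q, R = np.linalg.qr(rng.standard_normal((p, d)))
    return Q * np.sign(np.diag(R))


def planted_instance(rng, p=(6, 7), d0=2, d_spec=(2, 1), n=12, scale=3.0):
    """Noiseless views X_v = P*_v [C*; S*_v] with known ground truth parts."""
    C = scale * rng.standard_normal((d0, n))
    P, S, X = [], [], []
    for p_v, d_v in zip(p, d_spec):
        P_v = random_orthonormal(rng, p_v, d0 + d_v)
        S_v = scale * rng.standard_normal((d_v, n))
        P.append(P_v)
        S.append(S_v)
        X.append(P_v @ np.vstack([C, S_v]))
    return ViewSet(X), P, C, S


def random_decomposition(rng, views, d0, d_spec):
    """Valid (orthonormal-basis) decomposition with random representations."""
    P = [
        random_orthonormal(rng, p_v, d0 + d_v)
        for p_v, d_v in zip(views.p, d_spec)
    ]
    C = rng.standard_normal((d0, views.n))
    S = [rng.standard_normal((d_v, views.n)) for d_v in d_spec]
    return Decomposition(P=P, C=C, S=S, d0=d0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blobs():
    """Two far-separated tight clusters in 2-D, 20 samples each (d x n)."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.05, size=(2, 20))
    b = rng.normal(0.0, 0.05, size=(2, 20)) + np.array([[10.0], [0.0]])
    rep = np.hstack([a, b])
    truth = np.repeat([0, 1], 20)
    return rep, truth


@pytest.fixture
def dims22():
    return Dimensions(d0=2, d_spec=(2, 2), beta=1.0)
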