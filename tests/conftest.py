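import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_distances(X, metric="euclidean"):
    """Element-wise double-loop distance oracle, independent of the package."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = X[i], X[j]
            if metric == "euclidean":
                D[i, j] = np.sqrt(np.sum((a - b) ** 2))
            elif metric == "cosine":
                D[i, j] = 1.0 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            elif metric == "correlation":
                ac, bc = a - a.mean(), b - b.mean()
                D[i, j] = 1.0 - (ac @ bc) / (np.linalg.norm(ac) * np.linalg.norm(bc))
    return D


def brute_force_stress(DX, DY, W=None):
    """Double-loop ordered-pair stress oracle."""
    DX, DY = np.asarray(DX), np.asarray(DY)
    total = 0.0
    n = DX.shape[0]
    for i in range(n):
        for j in range(n):
            w = 1.0 if W is None else W[i, j]
            total += w * (DX[i, j] - DY[i, j]) ** 2
    return total
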