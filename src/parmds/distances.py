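"""Pairwise dissimilarities, the metric-MDS stress objective, and helpers.

The quantities here are the common currency of every embedding method in
this package: an ``n x m`` observation-by-feature matrix ``X`` (rows are
cells/points), its ``n x n`` distance matrix ``D_X`` under a named metric,
and the raw stress

    stress(D_X, D_Y) = sum_{i,j} w_ij ((D_X)_ij - (D_Y)_ij)^2

summed over *all ordered pairs* (both triangles and the zero diagonal), so
that with unit weights it equals the squared Frobenius norm ``||D_X -
D_Y||_F^2``.  This convention keeps identities such as ``||D_X||_F^2 =
2 n ||X||_F^2`` (valid for row-centered ``X``) literal.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "METRICS",
    "DENSE_CAP",
    "pairwise_distances",
    "stress",
    "stress_estimate",
    "sammon_weights",
    "center_rows",
    "intrinsic_dimension",
    "gram_from_distances",
]

METRICS = ("euclidean", "cosine", "correlation")

#: Largest n for which a dense n x n distance matrix is materialized.
DENSE_CAP = 20_000


def _as_dense_float(X) -> np.ndarray:
    """Coerce input (array-like or scipy sparse) to a dense float ndarray."""
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"matrix must be at least 1x1, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    return X


def _check_metric_rows(X: np.ndarray, metric: str) -> None:
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(
                f"cosine distance undefined for all-zero row (row {bad})"
            )
    elif metric == "correlation":
        if np.any(np.ptp(X, axis=1) == 0):
            bad = int(np.flatnonzero(np.ptp(X, axis=1) == 0)[0])
            raise ValueError(
                f"correlation distance undefined for constant row (row {bad})"
            )


def pairwise_distances(X, metric: str = "euclidean", *, cap: int = DENSE_CAP) -> np.ndarray:
    """Full symmetric ``n x n`` distance matrix of the rows of ``X``.

    Parameters
    ----------
    X : (n, m) array-like or sparse
        Observation-by-feature matrix.
    metric : {"euclidean", "cosine", "correlation"}
        ``cosine`` is 1 minus the cosine similarity; ``correlation`` is
        1 minus the Pearson correlation of the two rows.
    cap : int
        Refuse to materialize a dense matrix for ``n > cap``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = _as_dense_float(X)
    n = X.shape[0]
    if n > cap:
        raise ValueError(
            f"n={n} exceeds the dense distance-matrix cap ({cap}); "
            "use stress_estimate for sampled-pair estimates"
        )
    _check_metric_rows(X, metric)
    if n == 1:
        return np.zeros((1, 1))
    D = squareform(pdist(X, metric=metric))
    # pdist can return tiny negatives for cosine/correlation round-off
    np.maximum(D, 0.0, out=D)
    return D


def batch_cross_distances(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """Rectangular distance block ``d(a_i, b_j)`` used by minibatch training."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    D = cdist(A, B, metric=metric)
    return np.maximum(D, 0.0)


def stress(DX, DY, weights=None) -> float:
    """Raw stress between two distance matrices over all ordered pairs.

    Equals ``||DX - DY||_F^2`` when ``weights`` is None (all ones).
    ``weights`` must be a symmetric nonnegative ``n x n`` matrix.
    """
    DX = np.asarray(DX, dtype=float)
    DY = np.asarray(DY, dtype=float)
    if DX.shape != DY.shape:
        raise ValueError(f"shape mismatch: {DX.shape} vs {DY.shape}")
    diff2 = (DX - DY) ** 2
    if weights is None:
        return float(diff2.sum())
    W = np.asarray(weights, dtype=float)
    if W.shape != DX.shape:
        raise ValueError(f"weights shape {W.shape} does not match {DX.shape}")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    return float((W * diff2).sum())


def sammon_weights(DX) -> np.ndarray:
    """Sammon-mapping weight preset ``w_ij = 1 / (D_X)_ij`` with zero diagonal.

    Off-diagonal zero distances (duplicate points) also get weight 0.
    """
    DX = np.asarray(DX, dtype=float)
    with np.errstate(divide="ignore"):
        W = np.where(DX > 0, 1.0 / np.where(DX > 0, DX, 1.0), 0.0)
    return W


def stress_estimate(X, Y, metric: str = "euclidean", *, n_pairs: int = 200_000,
                    seed: int = 0) -> float:
    """Monte-Carlo estimate of the full ordered-pair stress from sampled pairs.

    For datasets above the dense cap the exact n x n stress is not
    materialized; instead ``n_pairs`` ordered pairs (i != j) are sampled
    uniformly and the mean squared distance discrepancy is rescaled by the
    total number of ordered pairs ``n^2``.  The value is an estimate, not
    the exact stress.
    """
    X = _as_dense_float(X)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    if metric == "euclidean":
        dx = np.linalg.norm(X[i] - X[j], axis=1)
    else:
        _check_metric_rows(X, metric)
        dx = np.array([
            batch_cross_distances(X[a:a + 1], X[b:b + 1], metric)[0, 0]
            for a, b in zip(i, j)
        ])
    dy = np.linalg.norm(Y[i] - Y[j], axis=1)
    mean_sq = float(np.mean((dx - dy) ** 2))
    return mean_sq * n * n


def center_rows(X) -> np.ndarray:
    """Subtract column means so every column of the result sums to zero."""
    X = _as_dense_float(X)
    return X - X.mean(axis=0, keepdims=True)


def intrinsic_dimension(X, variance_threshold: float = 0.95) -> int:
    """Smallest h with the top-h squared singular values holding >= threshold.

    The SVD is taken on the row-centered matrix, so the ratio is a variance
    ratio.  Used to size the hidden layer of the neural embedding.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    Xc = center_rows(X)
    s = np.linalg.svd(Xc, compute_uv=False)
    total = float(np.sum(s ** 2))
    if total == 0.0:
        raise ValueError("matrix has zero variance after centering")
    ratio = np.cumsum(s ** 2) / total
    return int(np.searchsorted(ratio, variance_threshold - 1e-12) + 1)


def gram_from_distances(D2) -> np.ndarray:
    """Double centering: map squared distances to a Gram matrix.

    Returns ``-1/2 H D2 H`` with ``H = I - (1/n) e e^T``.  When ``D2`` holds
    squared Euclidean distances of row-centered points, the result is the
    ``n x n`` Gram matrix of the rows, ``X X^T``.
    """
    D2 = np.asarray(D2, dtype=float)
    if D2.ndim != 2 or D2.shape[0] != D2.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {D2.shape}")
    if not np.allclose(D2, D2.T, atol=1e-8 * max(1.0, np.abs(D2).max())):
        raise ValueError("squared-distance matrix must be symmetric")
    # H D2 H expanded: subtract row means, column means, add grand mean
    row_mean = D2.mean(axis=1, keepdims=True)
    col_mean = D2.mean(axis=0, keepdims=True)
    grand = D2.mean()
    return -0.5 * (D2 - row_mean - col_mean + grand)
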