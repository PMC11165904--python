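"""Projected metric MDS: distance-preserving embedding constrained to a
linear map.

Projected metric MDS sits between classical MDS (which yields a linear map
but optimizes inner products) and metric MDS (which optimizes distances but
yields no map): it minimizes the metric-MDS stress

    min_P  || D_X - D_{XP} ||_F^2

over an ``m x k`` projection matrix ``P``, so the embedding is ``Y = XP``.
Two results make the problem tractable and quantifiable:

* Given any target configuration ``Y~``, the least-squares-closest linear
  image ``min_P ||Y~ - XP||_F^2`` has the closed-form solution
  ``P~ = V1 Sigma~^{-1} U1^T Y~`` from the thin SVD of ``X`` restricted to
  its r nonzero singular values, with residual ``||U2^T Y~||_F^2``.
* For row-centered ``X`` that construction obeys the approximation bound
  ``||D_{Y~} - D_{XP~}||_F <= sqrt(n - r + 2) ||D_{Y~}||_F``, so a linear
  map can never be worse than the target configuration by more than this
  rank-dependent factor.

The stress objective itself is minimized by L-BFGS from a PCA
initialization, with each output distance smoothed as ``sqrt(||.||^2 +
eps)`` to keep the objective differentiable at coincident points.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .baselines import pca_embed
from .distances import _as_dense_float, center_rows, pairwise_distances, stress

__all__ = [
    "least_squares_projection",
    "numerical_rank",
    "ProjectedMDS",
    "solve_projected_mmds",
    "projection_bound_check",
]


def numerical_rank(s: np.ndarray, n: int, m: int, tol: float | None = None) -> int:
    """Rank from singular values with tolerance sigma_1 * max(n, m) * eps."""
    if s.size == 0 or s[0] == 0:
        return 0
    if tol is None:
        tol = s[0] * max(n, m) * np.finfo(float).eps
    return int(np.sum(s > tol))


def least_squares_projection(X, Y_tilde, tol: float | None = None):
    """Closed-form minimizer of ``||Y~ - XP||_F^2``.

    Returns ``(P_tilde, residual)`` where ``P~ = V1 Sigma~^{-1} U1^T Y~``
    uses only the nonzero singular triplets of ``X`` (rank decided by
    ``tol``, default ``sigma_1 * max(n, m) * machine eps``) and the
    residual equals ``||U2^T Y~||_F^2``.  Rank deficiency is handled by the
    pseudo-inverse construction; no error paths.
    """
    X = _as_dense_float(X)
    Y_tilde = np.asarray(Y_tilde, dtype=float)
    if Y_tilde.shape[0] != X.shape[0]:
        raise ValueError("X and Y_tilde must have the same number of rows")
    U, s, Vt = np.linalg.svd(X, full_matrices=True)
    r = numerical_rank(s, *X.shape, tol=tol)
    if r == 0:
        P = np.zeros((X.shape[1], Y_tilde.shape[1]))
        return P, float(np.sum(Y_tilde ** 2))
    U1 = U[:, :r]
    V1 = Vt[:r].T
    P = V1 @ ((U1.T @ Y_tilde) / s[:r, None])
    U2 = U[:, r:]
    residual = float(np.sum((U2.T @ Y_tilde) ** 2))
    return P, residual


class ProjectedMDS(BaseEstimator, TransformerMixin):
    """Linear-map metric MDS fitted by smoothed L-BFGS from PCA.

    Parameters
    ----------
    n_components : output dimension k.
    epsilon : smoothing constant; each output distance is computed as
        ``sqrt(||y_i - y_j||^2 + epsilon)`` so the objective is
        differentiable at coincident points.
    max_iter, tol : L-BFGS iteration cap and relative-objective-change
        convergence threshold.

    Attributes
    ----------
    projection_ : (m, k) matrix P; ``transform`` maps centered rows by it.
    embedding_ : (n, k) embedding of the training data.
    objective_trace_ : smoothed objective at each accepted iterate
        (non-increasing; the first entry is the PCA initialization).
    """

    def __init__(self, n_components: int = 2, epsilon: float = 1e-6,
                 max_iter: int = 500, tol: float = 1e-8):
        self.n_components = n_components
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.tol = tol

    def _objective_grad(self, p_flat, Xc, DX, shape):
        P = p_flat.reshape(shape)
        Y = Xc @ P
        diff = Y[:, None, :] - Y[None, :, :]
        S = np.sum(diff * diff, axis=2)
        DYs = np.sqrt(S + self.epsilon)
        R = DYs - DX
        f = float(np.sum(R * R))
        # d f / d y_i over ordered pairs: each unordered pair appears twice
        A = 4.0 * R / DYs
        np.fill_diagonal(A, 0.0)
        G = (A[:, :, None] * diff).sum(axis=1)
        g = Xc.T @ G
        return f, g.ravel()

    def fit(self, X, y=None):
        X = _as_dense_float(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 points")
        self.column_means_ = X.mean(axis=0)
        Xc = X - self.column_means_
        DX = pairwise_distances(Xc)
        k = self.n_components
        _, P0 = pca_embed(Xc, k)

        shape = P0.shape
        trace = [self._objective_grad(P0.ravel(), Xc, DX, shape)[0]]

        def cb(pk):
            trace.append(self._objective_grad(pk, Xc, DX, shape)[0])

        res = minimize(
            self._objective_grad, P0.ravel(), args=(Xc, DX, shape),
            jac=True, method="L-BFGS-B", callback=cb,
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        if not np.isfinite(res.fun):
            raise FloatingPointError("projected-MDS objective became non-finite")
        # L-BFGS line search only accepts decreases, but keep the best seen
        self.projection_ = res.x.reshape(shape)
        self.embedding_ = Xc @ self.projection_
        self.objective_ = float(res.fun)
        self.objective_trace_ = np.asarray(trace)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "projection_")
        X = _as_dense_float(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        return (X - self.column_means_) @ self.projection_

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def solve_projected_mmds(X, k: int, epsilon: float = 1e-6, seed: int = 0):
    """Functional wrapper over :class:`ProjectedMDS`.

    Returns ``(P, embedding, objective_trace)``.  The optimizer is
    deterministic (PCA start), so ``seed`` is accepted for interface
    uniformity but unused.
    """
    model = ProjectedMDS(n_components=k, epsilon=epsilon).fit(X)
    return model.projection_, model.embedding_, model.objective_trace_


def projection_bound_check(X, Y_tilde, tol: float | None = None) -> dict:
    """Check the rank-dependent linear-approximation bound.

    For row-centered ``X`` (centered internally otherwise) and an arbitrary
    candidate configuration ``Y~``, computes the closed-form ``P~`` and
    reports ``lhs = ||D_{Y~} - D_{XP~}||_F``, ``rhs = sqrt(n - r + 2) *
    ||D_{Y~}||_F`` with ``r = rank(X)``, and whether ``lhs <= rhs``.
    """
    X = center_rows(X)
    Y_tilde = np.asarray(Y_tilde, dtype=float)
    P, _ = least_squares_projection(X, Y_tilde, tol=tol)
    s = np.linalg.svd(X, compute_uv=False)
    r = numerical_rank(s, *X.shape, tol=tol)
    DY = pairwise_distances(Y_tilde)
    DXP = pairwise_distances(X @ P)
    lhs = float(np.sqrt(stress(DY, DXP)))
    rhs = float(np.sqrt(X.shape[0] - r + 2) * np.sqrt(np.sum(DY ** 2)))
    return {"lhs": lhs, "rhs": rhs, "rank": r, "holds": bool(lhs <= rhs + 1e-9 * max(1.0, rhs))}
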