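"""Comparator embeddings: SMACOF, classical MDS/PCA, Gaussian random projection.

SMACOF ("Scaling by MAjorizing a COmplicated Function") minimizes metric-MDS
stress by iterated Guttman transforms; each transform is the exact minimizer
of a quadratic majorizer of the stress, so the stress trace is monotonically
non-increasing.  Classical MDS on explicitly given points is equivalent to
PCA: project the row-centered data onto its top-k right singular vectors.
Gaussian random projection multiplies by an i.i.d. normal matrix scaled by
1/sqrt(k), which preserves squared distances in expectation
(Johnson-Lindenstrauss).  PCA and random projection are linear, SMACOF is
not a map at all (it produces coordinates only for the points it was given);
all three serve as baselines for the parametric neural embedding.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.random_projection import GaussianRandomProjection

from .distances import DENSE_CAP, _as_dense_float, pairwise_distances, stress

__all__ = ["SMACOF", "smacof_embed", "pca_embed", "random_projection"]


def _classical_mds_config(D: np.ndarray, k: int) -> np.ndarray:
    """Classical-MDS coordinates from a distance matrix (top-k eigenpairs of
    the double-centered squared distances); used as SMACOF's default init."""
    from .distances import gram_from_distances

    B = gram_from_distances(D ** 2)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)


class SMACOF(BaseEstimator):
    """Metric MDS by stress majorization (unweighted Guttman transform).

    Operates on a precomputed distance matrix; ``fit`` stores the final
    configuration in ``embedding_`` and the per-iteration stress (ordered-
    pair convention, i.e. ``||D - D_Y||_F^2``) in ``stress_trace_``.
    Iterations stop when the relative stress change drops below ``tol`` or
    after ``max_iter`` transforms.  Zero distances in the current
    configuration contribute 0/0 terms to the transform; they are defined
    as 0.  Dense and quadratic in n, hence refused above ``size_cap``.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 300,
                 tol: float = 1e-6, init: str = "classical",
                 random_state: int = 0, size_cap: int = DENSE_CAP):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state
        self.size_cap = size_cap

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        if D.ndim != 2 or D.shape[1] != n:
            raise ValueError(f"expected a square distance matrix, got {D.shape}")
        if n < 2:
            raise ValueError("need at least 2 points")
        if n > self.size_cap:
            raise ValueError(
                f"n={n} exceeds the SMACOF size cap ({self.size_cap}); "
                "dense majorization is quadratic in n"
            )
        if not np.allclose(D, D.T) or np.any(D < 0) or np.any(np.diag(D) != 0):
            raise ValueError(
                "D must be symmetric and nonnegative with a zero diagonal"
            )
        k = self.n_components
        if self.init == "classical":
            Y = _classical_mds_config(D, k)
        elif self.init == "random":
            rng = np.random.default_rng(self.random_state)
            Y = rng.standard_normal((n, k)) * D[D > 0].mean() if np.any(D > 0) \
                else rng.standard_normal((n, k))
        else:
            raise ValueError("init must be 'classical' or 'random'")

        trace = []
        DY = pairwise_distances(Y, cap=self.size_cap)
        s = stress(D, DY)
        trace.append(s)
        for _ in range(self.max_iter):
            # Guttman transform: Y <- (1/n) B(Y) Y
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(DY > 0, D / np.where(DY > 0, DY, 1.0), 0.0)
            B = -ratio
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            Y = (B @ Y) / n
            DY = pairwise_distances(Y, cap=self.size_cap)
            s_new = stress(D, DY)
            trace.append(s_new)
            if s > 0 and (s - s_new) / s < self.tol:
                s = s_new
                break
            if s == 0:
                break
            s = s_new
        self.embedding_ = Y
        self.stress_ = s
        self.stress_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace) - 1
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_


def smacof_embed(D, k: int, max_iter: int = 300, tol: float = 1e-6,
                 seed: int = 0, init: str = "classical"):
    """Functional wrapper over :class:`SMACOF`; returns
    ``(embedding, stress_trace)``."""
    model = SMACOF(n_components=k, max_iter=max_iter, tol=tol, init=init,
                   random_state=seed).fit(D)
    return model.embedding_, model.stress_trace_


def pca_embed(X, k: int):
    """PCA / classical MDS on explicit points.

    Row-centers ``X`` and projects onto the top-k right singular vectors.
    Returns ``(embedding, loadings)`` with ``loadings`` of shape (m, k), so
    unseen points map linearly as ``(X_new - column_means) @ loadings``.
    """
    X = _as_dense_float(X)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n, m)={min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    return pca.transform(X), pca.components_.T


def random_projection(X, k: int, seed: int = 0):
    """Gaussian random projection to k dimensions.

    Entries of the (m, k) projection matrix are i.i.d. N(0, 1/k), so
    squared pairwise distances are preserved in expectation.  Returns
    ``(embedding, projection_matrix)``.
    """
    X = _as_dense_float(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    grp = GaussianRandomProjection(n_components=k, random_state=seed)
    Y = grp.fit_transform(X)
    return Y, grp.components_.T
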