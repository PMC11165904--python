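"""Seeded synthetic generators for exercising every embedding method.

Three generators cover the geometries the methods are meant to handle:

* ``open_box`` — points on the five faces of a lidless cube, the canonical
  example of a 2-manifold that no linear map can unfold but a nonlinear
  distance-preserving map can.
* ``gaussian_clusters`` — isotropic, well-separated blobs, the idealized
  "distinct cell populations" regime.
* ``scrna_like_counts`` — a sparse nonnegative integer count matrix with
  cluster-specific log-normal expression programs, emulating the shape and
  sparsity of single-cell RNA-seq data.  It is synthetic plumbing: it
  mimics marginal sparsity and cluster structure, not the full
  mean-variance relationship or batch effects of real scRNA-seq.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["LabeledDataset", "open_box", "gaussian_clusters", "scrna_like_counts"]


@dataclass
class LabeledDataset:
    """A data matrix with per-row integer labels and generation metadata."""

    X: object                     # (n, m) ndarray or scipy sparse matrix
    labels: np.ndarray            # (n,) integer labels
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def open_box(n: int, side: float = 1.0, seed: int = 0) -> LabeledDataset:
    """Uniform sample on the five faces of an open (lidless) axis-aligned box.

    The box is ``[0, side]^3`` with the top face (z = side) removed; the
    five remaining square faces have equal area so each receives points
    with probability 1/5.  Labels are the face index: 0 bottom (z=0),
    1 x=0, 2 x=side, 3 y=0, 4 y=side.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    rng = np.random.default_rng(seed)
    face = rng.integers(0, 5, size=n)
    u = rng.uniform(0.0, side, size=n)
    v = rng.uniform(0.0, side, size=n)
    X = np.empty((n, 3))
    bottom = face == 0
    X[bottom] = np.column_stack([u[bottom], v[bottom], np.zeros(bottom.sum())])
    for f, (axis, val) in enumerate(
        [(0, 0.0), (0, side), (1, 0.0), (1, side)], start=1
    ):
        m = face == f
        pts = np.empty((m.sum(), 3))
        pts[:, axis] = val
        free = [a for a in (0, 1, 2) if a != axis]
        pts[:, free[0]] = u[m]
        pts[:, free[1]] = v[m]
        X[m] = pts
    return LabeledDataset(X, face.astype(int),
                          {"kind": "open_box", "n": n, "side": side, "seed": seed})


def gaussian_clusters(n: int, m: int = 20, c: int = 4, separation: float = 10.0,
                      seed: int = 0) -> LabeledDataset:
    """Balanced isotropic unit-variance Gaussian blobs.

    Cluster centers are drawn at random and rescaled so every pair of
    centers is at least ``separation`` apart (in units of the within-
    cluster standard deviation, which is 1).  Sizes are balanced up to the
    remainder ``n mod c``.
    """
    if c < 1 or n < c:
        raise ValueError("need c >= 1 and n >= c")
    rng = np.random.default_rng(seed)
    if c == 1:
        centers = np.zeros((1, m))
    else:
        centers = rng.standard_normal((c, m))
        from scipy.spatial.distance import pdist

        dmin = pdist(centers).min()
        while dmin == 0:  # astronomically unlikely; regenerate
            centers = rng.standard_normal((c, m))
            dmin = pdist(centers).min()
        centers *= separation / dmin
    sizes = np.full(c, n // c)
    sizes[: n % c] += 1
    labels = np.repeat(np.arange(c), sizes)
    X = centers[labels] + rng.standard_normal((n, m))
    return LabeledDataset(X, labels,
                          {"kind": "gaussian_clusters", "n": n, "m": m, "c": c,
                           "separation": separation, "seed": seed})


def scrna_like_counts(n_cells: int = 500, n_genes: int = 2000, c: int = 3,
                      seed: int = 0) -> LabeledDataset:
    """Sparse synthetic count matrix with cluster-specific expression programs.

    Each gene g has a baseline rate drawn log-normally; each cluster
    up-regulates its own random 5% marker-gene set eight-fold.  Per-cell
    library-size factors are log-normal, and counts are Poisson draws from
    rate * factor, which at the defaults leaves >= 80% of entries zero.
    Returned as a CSR sparse matrix (writable as Matrix Market).

    Synthetic plumbing: matches the sparsity and block structure of
    droplet scRNA-seq, not its full noise model.
    """
    if c < 1 or n_cells < c:
        raise ValueError("need c >= 1 and n_cells >= c")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=-2.5, sigma=1.2, size=n_genes)
    programs = np.tile(base, (c, 1))
    n_markers = max(1, n_genes // 20)
    for j in range(c):
        markers = rng.choice(n_genes, size=n_markers, replace=False)
        programs[j, markers] *= 8.0
    sizes = np.full(c, n_cells // c)
    sizes[: n_cells % c] += 1
    labels = np.repeat(np.arange(c), sizes)
    lib = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    rates = programs[labels] * lib[:, None]
    counts = rng.poisson(rates)
    X = sp.csr_matrix(counts)
    return LabeledDataset(X, labels,
                          {"kind": "scrna_like_counts", "n_cells": n_cells,
                           "n_genes": n_genes, "c": c, "seed": seed})
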