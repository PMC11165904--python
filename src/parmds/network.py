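"""Minibatch Siamese neural network for metric MDS with an out-of-sample map.

The embedding is a fully-connected network with a single tanh hidden layer
and a linear output layer,

    y = tanh(x W1 + b1) W2 + b2,

trained to preserve pairwise distances: within each minibatch of ``b``
points the loss is

    sum_{i<j} ( d(x_i, x_j) - ||y_i - y_j|| )^2,

the input-space distance ``d`` being the configured metric and the
output-space distance always Euclidean.  Rows are reshuffled every epoch so
the sampled pairs form an unbiased estimate of the full distance matrix;
weights are updated with Adam.  Because the map is parametric, unseen
points are embedded by a pure forward pass (``transform``) without
re-optimization — the property that distinguishes this approach from
SMACOF, which only produces coordinates for the training points.

The hidden width defaults to an estimate of the data's intrinsic dimension
(smallest number of top singular values retaining 95% of the variance),
never below the output dimension.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .distances import (
    METRICS,
    _as_dense_float,
    batch_cross_distances,
    intrinsic_dimension,
)

__all__ = ["NeuralMDS", "init_network", "batch_pair_loss", "fit_nn_mds"]

MODEL_FORMAT_VERSION = 1


def init_network(m: int, h: int, k: int, seed: int):
    """Seeded symmetric scaled-uniform (Glorot) initialization.

    Weights are drawn from U(-a, a) with a = sqrt(6 / (fan_in + fan_out));
    biases start at zero.  Identical seeds give identical parameters.
    Returns ``(W1, b1, W2, b2)`` with shapes (m,h), (h,), (h,k), (k,).
    """
    if m < 1 or h < 1 or k < 1:
        raise ValueError(f"dimensions must be positive, got m={m}, h={h}, k={k}")
    rng = np.random.default_rng(seed)
    a1 = np.sqrt(6.0 / (m + h))
    a2 = np.sqrt(6.0 / (h + k))
    W1 = rng.uniform(-a1, a1, size=(m, h))
    b1 = np.zeros(h)
    W2 = rng.uniform(-a2, a2, size=(h, k))
    b2 = np.zeros(k)
    return W1, b1, W2, b2


def batch_pair_loss(X_batch, Y_batch, metric: str = "euclidean") -> float:
    """Siamese pair loss of a batch: sum over unordered pairs i<j of
    ``(d_metric(x_i, x_j) - ||y_i - y_j||)^2``."""
    X_batch = np.asarray(X_batch, dtype=float)
    Y_batch = np.asarray(Y_batch, dtype=float)
    b = X_batch.shape[0]
    if b < 2:
        raise ValueError("a batch needs at least 2 points to form a pair")
    if Y_batch.shape[0] != b:
        raise ValueError("X_batch and Y_batch row counts differ")
    DX = batch_cross_distances(X_batch, X_batch, metric)
    DY = batch_cross_distances(Y_batch, Y_batch, "euclidean")
    iu = np.triu_indices(b, k=1)
    return float(np.sum((DX[iu] - DY[iu]) ** 2))


class NeuralMDS(BaseEstimator, TransformerMixin):
    """Metric MDS via a two-layer Siamese network, scikit-learn style.

    Parameters
    ----------
    n_components : int
        Output dimension k.
    hidden : "auto" or int
        Hidden-layer width; "auto" uses the intrinsic-dimension estimate at
        95% retained variance, raised to ``n_components`` if smaller (a
        bottleneck narrower than the output is never useful).
    epochs, batch_size, learning_rate : training schedule; Adam optimizer.
        The per-batch loss is summed over the batch's unordered pairs
        unless ``average_pairs`` is set (averaging only rescales the
        gradient).
    metric : {"euclidean", "cosine", "correlation"}
        Input-space distance preserved by the embedding.
    standardize : bool
        Optionally z-score features before training; the fitted means and
        scales are stored so ``transform`` applies the identical path.
    random_state : int
        Single seed stream governing initialization and epoch shuffling.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : network parameters.
    hidden_dim_ : resolved hidden width.
    embedding_ : (n, k) embedding of the training data.
    loss_trace_ : per-epoch mean batch loss.
    """

    def __init__(self, n_components: int = 2, hidden="auto", epochs: int = 1000,
                 batch_size: int = 256, learning_rate: float = 1e-2,
                 metric: str = "euclidean", standardize: bool = False,
                 average_pairs: bool = False, random_state: int = 0):
        self.n_components = n_components
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.metric = metric
        self.standardize = standardize
        self.average_pairs = average_pairs
        self.random_state = random_state

    # ---- internals ----------------------------------------------------

    def _forward(self, X):
        H = np.tanh(X @ self.W1_ + self.b1_)
        return H, H @ self.W2_ + self.b2_

    def _preprocess(self, X):
        if self.standardize:
            return (X - self.mean_) / self.scale_
        return X

    def _validate(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    # ---- estimator API -------------------------------------------------

    def fit(self, X, y=None):
        self._validate()
        X = _as_dense_float(X)
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 points to fit")
        k = self.n_components

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        Xp = self._preprocess(X)

        if self.hidden == "auto":
            h = max(intrinsic_dimension(Xp, 0.95), k)
        else:
            h = int(self.hidden)
            if h < 1:
                raise ValueError("hidden must be 'auto' or a positive integer")
        self.hidden_dim_ = h
        self.n_features_in_ = m

        self.W1_, self.b1_, self.W2_, self.b2_ = init_network(
            m, h, k, self.random_state
        )

        # Adam state, one slot per parameter array
        params = [self.W1_, self.b1_, self.W2_, self.b2_]
        mom = [np.zeros_like(p) for p in params]
        vel = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        rng = np.random.default_rng(self.random_state)
        bs = min(self.batch_size, n)
        trace = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                if idx.size < 2:  # a lone trailing point forms no pair
                    continue
                Xb = Xp[idx]
                loss, grads = self._batch_loss_and_grads(Xb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; "
                        "try a smaller learning rate"
                    )
                batch_losses.append(loss)
                t += 1
                for p, g, mo, ve in zip(params, grads, mom, vel):
                    mo *= beta1
                    mo += (1 - beta1) * g
                    ve *= beta2
                    ve += (1 - beta2) * g * g
                    mhat = mo / (1 - beta1 ** t)
                    vhat = ve / (1 - beta2 ** t)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            trace.append(float(np.mean(batch_losses)))
        self.loss_trace_ = np.asarray(trace)
        _, self.embedding_ = self._forward(Xp)
        return self

    def _batch_loss_and_grads(self, Xb):
        """Loss and analytic gradients of the pair loss on one batch."""
        b = Xb.shape[0]
        H, Y = self._forward(Xb)
        DX = batch_cross_distances(Xb, Xb, self.metric)
        diff = Y[:, None, :] - Y[None, :, :]        # (b, b, k)
        DY = np.sqrt(np.sum(diff * diff, axis=2))
        iu = np.triu_indices(b, k=1)
        loss = float(np.sum((DX[iu] - DY[iu]) ** 2))
        npairs = b * (b - 1) // 2
        scale = 1.0 / npairs if self.average_pairs else 1.0
        # dL/dy_i = sum_{j != i} 2 (dy_ij - dx_ij) (y_i - y_j) / dy_ij
        safe = np.where(DY > 0, DY, 1.0)
        A = 2.0 * (DY - DX) / safe
        np.fill_diagonal(A, 0.0)
        G = (A[:, :, None] * diff).sum(axis=1) * scale   # (b, k)
        gW2 = H.T @ G
        gb2 = G.sum(axis=0)
        dH = G @ self.W2_.T
        dZ = dH * (1.0 - H * H)
        gW1 = Xb.T @ dZ
        gb1 = dZ.sum(axis=0)
        return loss * scale, (gW1, gb1, gW2, gb2)

    def transform(self, X):
        """Embed (possibly unseen) points by a pure forward pass."""
        check_is_fitted(self, "W1_")
        X = _as_dense_float(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        _, Y = self._forward(self._preprocess(X))
        return Y

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    # ---- persistence ---------------------------------------------------

    def save(self, path):
        """Serialize the fitted model to a portable JSON container."""
        check_is_fitted(self, "W1_")
        blob = {
            "format_version": MODEL_FORMAT_VERSION,
            "params": self.get_params(),
            "input_dim": self.n_features_in_,
            "hidden_dim": self.hidden_dim_,
            "output_dim": self.n_components,
            "W1": self.W1_.tolist(),
            "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(),
            "b2": self.b2_.tolist(),
            "mean": self.mean_.tolist() if self.standardize else None,
            "scale": self.scale_.tolist() if self.standardize else None,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path):
        """Load a model saved by :meth:`save`; transform round-trips exactly."""
        with open(path) as fh:
            blob = json.load(fh)
        major = int(blob.get("format_version", 0))
        if major > MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version {major} is newer than supported "
                f"({MODEL_FORMAT_VERSION})"
            )
        model = cls(**blob["params"])
        model.n_features_in_ = int(blob["input_dim"])
        model.hidden_dim_ = int(blob["hidden_dim"])
        model.W1_ = np.asarray(blob["W1"], dtype=float)
        model.b1_ = np.asarray(blob["b1"], dtype=float)
        model.W2_ = np.asarray(blob["W2"], dtype=float)
        model.b2_ = np.asarray(blob["b2"], dtype=float)
        if model.standardize:
            model.mean_ = np.asarray(blob["mean"], dtype=float)
            model.scale_ = np.asarray(blob["scale"], dtype=float)
        return model


def fit_nn_mds(X, n_components: int = 2, **kwargs):
    """Functional wrapper: fit a :class:`NeuralMDS` and return
    ``(model, embedding)``."""
    model = NeuralMDS(n_components=n_components, **kwargs).fit(X)
    return model, model.embedding_
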