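"""From-scratch self-organizing map on a 2-D rectangular grid.

The map is a (Dx x Dy) grid of neurons, each holding a weight vector in
feature space. Training presents observations one at a time (online): the
best matching unit (BMU) — the neuron with the nearest weight vector — and
its grid neighbors move toward the observation, with a Gaussian
neighborhood whose width and a learning rate that both decay linearly over
epochs. After training, each observation is assigned the label of its BMU
and that neuron's grid coordinate (x, y).

Neuron indices are 1-based and map to grid coordinates as
``x = 1 + (idx-1) mod Dx``, ``y = 1 + floor((idx-1) / Dx)``; for a 2x2 grid
index 1 -> (1,1), 2 -> (2,1), 3 -> (1,2), 4 -> (2,2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "SelfOrganizingMap",
    "ClusterAssignment",
    "find_bmu",
    "neuron_coordinates",
]


def neuron_coordinates(dims) -> np.ndarray:
    """1-based grid coordinate (x, y) of each neuron index 1..Dx*Dy."""
    dx, dy = dims
    idx = np.arange(dx * dy)
    return np.stack([1 + (idx % dx), 1 + (idx // dx)], axis=1)


def find_bmu(weights: np.ndarray, x: np.ndarray) -> int:
    """Best matching unit: 1-based index of the nearest weight row.

    Ties are broken toward the lowest index.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector must be finite")
    if x.shape != (weights.shape[1],):
        raise ValueError("input dimension does not match weights")
    d2 = ((weights - x) ** 2).sum(axis=1)
    return int(np.argmin(d2)) + 1


@dataclass
class ClusterAssignment:
    """Per-observation cluster label and grid coordinate."""

    labels: np.ndarray  # 1-based neuron index per observation
    coords: np.ndarray  # (n_obs, 2) grid coordinates (x, y)
    subject_ids: np.ndarray = None
    run_ids: np.ndarray = None


class SelfOrganizingMap(ClusterMixin, BaseEstimator):
    """Online-trained SOM with rectangular topology.

    Parameters
    ----------
    dims : tuple (Dx, Dy), default=(2, 2)
        Grid layout; Dx * Dy neurons.
    epochs : int, default=200
        Full passes over the (seeded shuffled) training set.
    init : {"sample", "linear"}, default="sample"
        "sample" initializes weights from data rows drawn without
        replacement (with replacement, warned, when there are more neurons
        than observations); "linear" spreads the grid over the plane of the
        top two principal axes.
    alpha : tuple (start, end), default=(0.5, 0.01)
        Learning rate, decayed linearly over epochs.
    sigma : tuple (start, end) or None
        Gaussian neighborhood radius in grid units, decayed linearly;
        defaults to (max(Dx, Dy) / 2, 0.5).
    random_state : int or None
        Seed for initialization and per-epoch shuffling.

    Attributes
    ----------
    weights_ : ndarray of shape (Dx*Dy, n_features)
    labels_ : ndarray
        1-based BMU label of each training observation.
    coords_ : ndarray of shape (n_obs, 2)
        Grid coordinate of each training observation.
    quantization_errors_ : ndarray of shape (epochs,)
        Mean BMU distance after each epoch.
    """

    def __init__(
        self,
        dims=(2, 2),
        epochs=200,
        init="sample",
        alpha=(0.5, 0.01),
        sigma=None,
        random_state=None,
    ):
        self.dims = dims
        self.epochs = epochs
        self.init = init
        self.alpha = alpha
        self.sigma = sigma
        self.random_state = random_state

    # -- initialization -------------------------------------------------
    def _init_weights(self, X, rng):
        k = self.dims[0] * self.dims[1]
        if self.init == "sample":
            if k > X.shape[0]:
                warnings.warn(
                    "more neurons than observations: sampling initial "
                    "weights with replacement",
                    stacklevel=2,
                )
                rows = rng.integers(0, X.shape[0], size=k)
            else:
                rows = rng.choice(X.shape[0], size=k, replace=False)
            return X[rows].copy()
        if self.init == "linear":
            mean = X.mean(axis=0)
            xc = X - mean
            # top-2 principal axes scaled by singular values
            _, s, vt = np.linalg.svd(xc, full_matrices=False)
            coords = neuron_coordinates(self.dims).astype(float)
            span = []
            for j, d in enumerate(self.dims):
                c = coords[:, j]
                span.append(np.zeros_like(c) if d == 1 else (2 * (c - 1) / (d - 1) - 1))
            scale = s[:2] / np.sqrt(max(X.shape[0] - 1, 1))
            w = mean + np.outer(span[0], scale[0] * vt[0])
            if vt.shape[0] > 1:
                w = w + np.outer(span[1], scale[1] * vt[1])
            return w
        raise ValueError(f"unknown init {self.init!r}")

    # -- training -------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        dx, dy = self.dims
        if dx < 1 or dy < 1:
            raise ValueError("dims must be >= 1 in both directions")
        rng = np.random.default_rng(self.random_state)
        w = self._init_weights(X, rng)
        coords = neuron_coordinates(self.dims).astype(float)
        grid_d2 = cdist(coords, coords, "sqeuclidean")

        a0, a1 = self.alpha
        s0, s1 = self.sigma if self.sigma is not None else (max(dx, dy) / 2.0, 0.5)
        n, e = X.shape[0], self.epochs
        qe = np.empty(e)
        for t in range(e):
            frac = t / (e - 1) if e > 1 else 0.0
            alpha_t = a0 + (a1 - a0) * frac
            sigma_t = s0 + (s1 - s0) * frac
            order = rng.permutation(n)
            neigh = np.exp(-grid_d2 / (2.0 * sigma_t**2))
            for i in order:
                x = X[i]
                d2 = ((w - x) ** 2).sum(axis=1)
                bmu = int(np.argmin(d2))
                w += (alpha_t * neigh[bmu])[:, None] * (x - w)
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(f"non-finite weights at epoch {t + 1}")
            qe[t] = cdist(X, w).min(axis=1).mean()

        self.weights_ = w
        self.quantization_errors_ = qe
        self.epochs_trained_ = e
        self.n_features_in_ = X.shape[1]
        self.grid_coords_ = neuron_coordinates(self.dims)
        self.labels_ = self.predict(X)
        self.coords_ = self.grid_coords_[self.labels_ - 1]
        return self

    def predict(self, X):
        """1-based BMU label per observation (ties to the lowest index)."""
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        d = cdist(X, self.weights_)
        return np.argmin(d, axis=1) + 1

    def assign(self, X, subject_ids=None, run_ids=None) -> ClusterAssignment:
        """Full assignment: labels plus grid coordinates, ids carried through."""
        labels = self.predict(X)
        return ClusterAssignment(
            labels=labels,
            coords=self.grid_coords_[labels - 1],
            subject_ids=subject_ids,
            run_ids=run_ids,
        )
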