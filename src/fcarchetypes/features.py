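"""Connectome feature construction and reduction.

Turns stacks of per-(subject, run) functional connectomes into the reduced
feature matrix used for clustering: Fisher z transform, lower-triangle
vectorization, PCA, and Monte-Carlo (Horn) parallel analysis to decide how
many principal components to retain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "ConnectomeSet",
    "ReducedFeatures",
    "ParallelAnalysisPCA",
    "fisher_z",
    "inverse_fisher_z",
    "vectorize_lower_triangle",
    "devectorize_lower_triangle",
    "parallel_analysis",
    "null_eigenvalue_thresholds",
    "reduce_dataset",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class ConnectomeSet:
    """Stack of per-(subject, run) symmetric connectivity matrices.

    Matrices are expected in Fisher-z units (edge weight = arctanh of the
    Pearson correlation between two parcels' time series).

    Parameters
    ----------
    matrices : ndarray of shape (n_obs, n_nodes, n_nodes)
        Symmetric matrices with zero diagonal (within ``1e-10``).
    subject_ids, run_ids : ndarray of shape (n_obs,)
        Identifiers carried through the whole pipeline.
    node_labels : list of str, optional
        One label per parcel; defaults to ``node_000`` style names.
    network_map : dict, optional
        Maps node label -> network (or block) name, used for re-ordering
        archetype summaries.
    """

    matrices: np.ndarray
    subject_ids: np.ndarray
    run_ids: np.ndarray
    node_labels: list = field(default=None)
    network_map: dict = field(default=None)

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (n_obs, N, N)")
        if not np.all(np.isfinite(self.matrices)):
            raise ValueError("connectome matrices must be finite")
        asym = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrices not symmetric (max asymmetry {asym:.3g})")
        self.subject_ids = np.asarray(self.subject_ids)
        self.run_ids = np.asarray(self.run_ids)
        n = self.matrices.shape[0]
        if len(self.subject_ids) != n or len(self.run_ids) != n:
            raise ValueError("subject_ids/run_ids length must match n_obs")
        if self.node_labels is None:
            self.node_labels = [f"node_{i:03d}" for i in range(self.n_nodes)]

    @property
    def n_obs(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def to_vectors(self) -> np.ndarray:
        """Vectorize every matrix's lower triangle; shape (n_obs, N(N-1)/2)."""
        rows, cols = _lower_triangle_indices(self.n_nodes)
        return self.matrices[:, rows, cols]


@dataclass
class ReducedFeatures:
    """Observations x retained-component matrix of z-scored PCA scores."""

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    n_components: int
    subject_ids: np.ndarray = None
    run_ids: np.ndarray = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        mu = self.scores.mean(axis=0)
        sd = self.scores.std(axis=0)
        if np.abs(mu).max() > 1e-8 or np.abs(sd - 1).max() > 1e-6:
            raise ValueError("scores must be z-scored per component")


def fisher_z(r, clip: bool = False):
    """Fisher z transform, ``z = arctanh(r)``.

    Variance-stabilizing transform of a Pearson correlation. With
    ``clip=True``, correlations with ``|r| >= 1`` (possible on degenerate
    synthetic input) are clipped to ``+/-(1 - 1e-7)`` before transforming;
    otherwise they raise.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    elif np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1: Fisher z undefined (enable clip to proceed)")
    return np.arctanh(r)


def inverse_fisher_z(z):
    """Inverse Fisher transform, ``r = tanh(z)``."""
    return np.tanh(np.asarray(z, dtype=float))


def _lower_triangle_indices(n: int):
    # Column-major order within the lower triangle: (1,0),(2,0),...,(n-1,0),
    # (2,1),(3,1),... obtained by transposing the row-major upper triangle.
    cols, rows = np.triu_indices(n, k=1)
    return rows, cols


def vectorize_lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Flatten the strict lower triangle of a symmetric matrix.

    Entries are taken in column-major order within the lower triangle
    (all of column 0 top to bottom, then column 1, ...), giving a vector of
    length ``N(N-1)/2``. :func:`devectorize_lower_triangle` inverts it.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    if np.abs(matrix - matrix.T).max() > _SYMMETRY_TOL:
        raise ValueError("input must be symmetric")
    rows, cols = _lower_triangle_indices(matrix.shape[0])
    return matrix[rows, cols]


def devectorize_lower_triangle(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from its edge vector."""
    vec = np.asarray(vec, dtype=float)
    expected = n_nodes * (n_nodes - 1) // 2
    if vec.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {vec.shape}")
    out = np.zeros((n_nodes, n_nodes))
    rows, cols = _lower_triangle_indices(n_nodes)
    out[rows, cols] = vec
    out[cols, rows] = vec
    return out


def _correlation_eigenvalues(data: np.ndarray) -> np.ndarray:
    """Eigenvalues of the feature correlation matrix, descending.

    For n_features > n_obs the nonzero spectrum is computed from the
    observation-space Gram matrix of the standardized data (identical
    nonzero eigenvalues, far cheaper); trailing zeros pad to n_features.
    """
    n, p = data.shape
    sd = data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature column: correlation undefined")
    z = (data - data.mean(axis=0)) / sd
    if p <= n:
        c = (z.T @ z) / (n - 1)
        ev = np.linalg.eigvalsh(c)[::-1]
    else:
        g = (z @ z.T) / (n - 1)
        ev = np.linalg.eigvalsh(g)[::-1]
        ev = np.concatenate([ev, np.zeros(p - n)])
    return np.clip(ev, 0, None)


def null_eigenvalue_thresholds(
    n_obs: int,
    n_features: int,
    n_sim: int = 10_000,
    percentile: float = 95.0,
    seed=None,
) -> np.ndarray:
    """Per-rank percentile of null correlation eigenvalues.

    Simulates ``n_sim`` standard-normal datasets of shape
    ``(n_obs, n_features)`` and returns, for each eigenvalue rank, the
    requested percentile of the null distribution. Depends only on the data
    shape, so thresholds can be reused across datasets of identical shape.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    rng = np.random.default_rng(seed)
    k = min(n_obs, n_features)
    sims = np.empty((n_sim, k))
    for i in range(n_sim):
        x = rng.standard_normal((n_obs, n_features))
        sims[i] = _correlation_eigenvalues(x)[:k]
    thr = np.percentile(sims, percentile, axis=0)
    if n_features > k:
        thr = np.concatenate([thr, np.zeros(n_features - k)])
    return thr


def parallel_analysis(
    data: np.ndarray,
    n_sim: int = 10_000,
    percentile: float = 95.0,
    seed=None,
    thresholds: np.ndarray = None,
) -> int:
    """Horn parallel analysis: number of components to retain.

    Compares observed correlation-matrix eigenvalues rank-by-rank with the
    given percentile of eigenvalues from shape-matched standard-normal null
    data. Counting stops at the first rank that fails to exceed its null
    threshold, so the retained set is always a leading prefix.

    Parameters
    ----------
    thresholds : ndarray, optional
        Precomputed output of :func:`null_eigenvalue_thresholds` for this
        data shape; when given, no null simulation is run and ``n_sim`` /
        ``seed`` are ignored.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if p > n:
        warnings.warn(
            f"more features ({p}) than observations ({n}): correlation "
            "matrix is rank deficient",
            stacklevel=2,
        )
    observed = _correlation_eigenvalues(data)
    if thresholds is None:
        thresholds = null_eigenvalue_thresholds(n, p, n_sim, percentile, seed)
    n_retain = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            n_retain += 1
        else:
            break
    return n_retain


class ParallelAnalysisPCA(TransformerMixin, BaseEstimator):
    """PCA with component count selected by Monte-Carlo parallel analysis.

    Fits an SVD-based PCA on the centered data (no per-feature
    standardization: connectome edges are already on a common Fisher-z
    scale), retains the leading components whose correlation-matrix
    eigenvalues exceed the per-rank null percentile, and z-scores the
    retained scores.

    Parameters
    ----------
    n_sim : int, default=10000
        Number of Monte-Carlo null datasets.
    percentile : float, default=95.0
        Null percentile an observed eigenvalue must exceed.
    random_state : int or None
        Seed for the null simulation.
    thresholds : ndarray, optional
        Precomputed null thresholds for this data shape (bypasses the
        simulation).

    Attributes
    ----------
    n_components_ : int
        Retained component count (>= 1; if parallel analysis retains
        nothing, one component is kept with a warning).
    eigenvalues_ : ndarray
        Covariance eigenvalues (PCA explained variances), non-increasing.
    loadings_ : ndarray of shape (n_components_, n_features)
    scale_mean_, scale_sd_ : ndarray
        Per-component training score mean/sd used for z-scoring.
    """

    def __init__(self, n_sim=10_000, percentile=95.0, random_state=None, thresholds=None):
        self.n_sim = n_sim
        self.percentile = percentile
        self.random_state = random_state
        self.thresholds = thresholds

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with >= 2 observations")
        variances = X.var(axis=0)
        # relative tolerance: numerically-constant columns carry only
        # amplified rounding noise once standardized
        keep = variances > 1e-13 * max(variances.max(), 1e-300)
        if not np.any(keep):
            raise ValueError("all feature columns are constant; PCA undefined")
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} constant feature column(s)",
                stacklevel=2,
            )
        self.feature_mask_ = keep
        Xk = X[:, keep]
        self.n_features_in_ = X.shape[1]
        n_retain = parallel_analysis(
            Xk,
            n_sim=self.n_sim,
            percentile=self.percentile,
            seed=self.random_state,
            thresholds=self.thresholds,
        )
        if n_retain == 0:
            warnings.warn(
                "parallel analysis retained no components; keeping 1",
                stacklevel=2,
            )
            n_retain = 1
        pca = PCA(n_components=min(Xk.shape[0] - 1, Xk.shape[1]), svd_solver="full")
        scores_all = pca.fit_transform(Xk)
        self.eigenvalues_ = pca.explained_variance_
        self.total_variance_ = float(Xk.var(axis=0, ddof=1).sum())
        numerical_rank = int(
            (self.eigenvalues_ > 1e-9 * self.eigenvalues_.sum()).sum()
        )
        if n_retain > numerical_rank:
            warnings.warn(
                f"retention capped at the numerical rank ({numerical_rank})",
                stacklevel=2,
            )
            n_retain = numerical_rank
        self.n_components_ = int(n_retain)
        self.loadings_ = pca.components_[:n_retain]
        self.mean_ = pca.mean_
        scores = scores_all[:, :n_retain]
        self.scale_mean_ = scores.mean(axis=0)
        self.scale_sd_ = scores.std(axis=0)
        if np.any(self.scale_sd_ == 0):
            raise ValueError("retained component with zero variance; data degenerate")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)[:, self.feature_mask_]
        scores = (X - self.mean_) @ self.loadings_.T
        return (scores - self.scale_mean_) / self.scale_sd_


def reduce_dataset(
    cs: ConnectomeSet,
    n_sim: int = 10_000,
    percentile: float = 95.0,
    seed=None,
    thresholds: np.ndarray = None,
) -> ReducedFeatures:
    """Full reduction: vectorize connectomes, PCA + parallel analysis, z-score."""
    vectors = cs.to_vectors()
    model = ParallelAnalysisPCA(
        n_sim=n_sim, percentile=percentile, random_state=seed, thresholds=thresholds
    )
    scores = model.fit(vectors).transform(vectors)
    return ReducedFeatures(
        scores=scores,
        loadings=model.loadings_,
        eigenvalues=model.eigenvalues_,
        n_components=model.n_components_,
        subject_ids=cs.subject_ids,
        run_ids=cs.run_ids,
    )
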