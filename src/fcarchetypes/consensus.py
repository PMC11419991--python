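"""Consensus clustering over repeated SOM trainings.

A single SOM training depends on its initialization and presentation
order. Robust archetypes are obtained by training an ensemble of
independently seeded SOMs, counting how often every pair of observations
lands in the same cluster (the consensus matrix), agglomerating the
co-assignment dissimilarity ``1 - M`` with average linkage, and cutting the
dendrogram at the grid's cluster count. The ensemble run that agrees best
(mean of ARI and AMI) with the consensus partition is the representative
run; its grid coordinates become the archetype coordinates used in all
downstream association analyses — which also resolves the SOM's inherent
label/axis exchangeability, since only that single run's coordinates are
ever interpreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .features import ConnectomeSet
from .som import SelfOrganizingMap, neuron_coordinates
from .stability import adjusted_mutual_information, adjusted_rand_index

__all__ = [
    "ConsensusSOM",
    "ConsensusResult",
    "ArchetypeSummary",
    "run_ensemble",
    "build_consensus_matrix",
    "consensus_partition",
    "select_representative_run",
    "summarize_archetypes",
]


def run_ensemble(features, dims, epochs, n_runs=100, seed=None, **som_kwargs):
    """Train ``n_runs`` independently seeded SOMs; stack their labels.

    Returns an (n_runs, n_obs) integer matrix of 1-based neuron labels and
    the list of fitted models (for coordinate lookup).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    features = np.asarray(features, dtype=float)
    root = np.random.SeedSequence(seed)
    labels, models = [], []
    for child in root.spawn(n_runs):
        som = SelfOrganizingMap(
            dims=dims,
            epochs=epochs,
            random_state=int(child.generate_state(1)[0] % (2**31)),
            **som_kwargs,
        )
        som.fit(features)
        labels.append(som.labels_)
        models.append(som)
    return np.asarray(labels), models


def build_consensus_matrix(labels: np.ndarray) -> np.ndarray:
    """Probability of co-assignment across runs.

    ``M[i, j]`` = fraction of runs in which observations i and j share a
    cluster label. Invariant to per-run label permutation; symmetric with
    unit diagonal.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] < 2:
        raise ValueError("labels must be (n_runs >= 2, n_obs)")
    n_runs, n_obs = labels.shape
    m = np.zeros((n_obs, n_obs))
    for row in labels:
        m += row[:, None] == row[None, :]
    return m / n_runs


def consensus_partition(m: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage dendrogram of ``1 - M`` into k clusters.

    Labels are canonicalized to 1..k in order of first appearance. If the
    cut yields fewer than k distinct groups (possible under heavy ties),
    the achieved number is returned with a warning.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("consensus matrix must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1:
        return np.ones(n, dtype=int)
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    achieved = len(np.unique(labels))
    if achieved < k:
        warnings.warn(
            f"consensus cut produced {achieved} < {k} clusters", stacklevel=2
        )
    # canonical relabeling by first appearance
    out = np.empty(n, dtype=int)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def select_representative_run(labels: np.ndarray, final_labels: np.ndarray) -> int:
    """Index of the ensemble run closest to the consensus partition.

    Argmax over runs of ``mean(ARI, AMI)`` against ``final_labels``; ties
    go to the lowest run index.
    """
    labels = np.asarray(labels)
    scores = [
        0.5
        * (
            adjusted_rand_index(row, final_labels)
            + adjusted_mutual_information(row, final_labels)
        )
        for row in labels
    ]
    return int(np.argmax(scores))


@dataclass
class ConsensusResult:
    """Bundle of all consensus outputs."""

    consensus_matrix: np.ndarray
    final_labels: np.ndarray
    representative_run: int
    representative_labels: np.ndarray
    representative_coords: np.ndarray
    per_run_agreement: np.ndarray  # (n_runs, 2): ARI, AMI vs final labels


class ConsensusSOM(ClusterMixin, BaseEstimator):
    """Consensus clustering estimator over an ensemble of SOMs.

    Parameters
    ----------
    dims : tuple (Dx, Dy), default=(2, 2)
    epochs : int, default=200
    n_runs : int, default=100
        Ensemble size.
    random_state : int or None
        Master seed; every ensemble member derives its own seed from it.
    som_params : dict, optional
        Extra keyword arguments forwarded to :class:`SelfOrganizingMap`.

    Attributes
    ----------
    consensus_matrix_ : ndarray (n_obs, n_obs)
    labels_ : ndarray
        Final consensus partition (1..k, canonical order).
    representative_run_ : int
        Index of the ensemble run most similar to the consensus.
    coords_ : ndarray (n_obs, 2)
        Grid coordinates from the representative run — the archetype
        (X, Y) coordinates used downstream.
    per_run_agreement_ : ndarray (n_runs, 2)
        ARI and AMI of each run against the consensus partition.
    """

    def __init__(self, dims=(2, 2), epochs=200, n_runs=100, random_state=None,
                 som_params=None):
        self.dims = dims
        self.epochs = epochs
        self.n_runs = n_runs
        self.random_state = random_state
        self.som_params = som_params

    def fit(self, X, y=None):
        som_kwargs = dict(self.som_params or {})
        labels, models = run_ensemble(
            X, self.dims, self.epochs, self.n_runs, self.random_state, **som_kwargs
        )
        k = self.dims[0] * self.dims[1]
        m = build_consensus_matrix(labels)
        final = consensus_partition(m, k)
        rep = select_representative_run(labels, final)
        coords = neuron_coordinates(self.dims)
        self.ensemble_labels_ = labels
        self.consensus_matrix_ = m
        self.labels_ = final
        self.representative_run_ = rep
        self.representative_model_ = models[rep]
        self.representative_labels_ = labels[rep]
        self.coords_ = coords[labels[rep] - 1]
        self.per_run_agreement_ = np.array(
            [
                [adjusted_rand_index(row, final), adjusted_mutual_information(row, final)]
                for row in labels
            ]
        )
        return self

    def result(self) -> ConsensusResult:
        return ConsensusResult(
            consensus_matrix=self.consensus_matrix_,
            final_labels=self.labels_,
            representative_run=self.representative_run_,
            representative_labels=self.representative_labels_,
            representative_coords=self.coords_,
            per_run_agreement=self.per_run_agreement_,
        )


@dataclass
class ArchetypeSummary:
    """Per-archetype mean connectomes and descriptive differences."""

    means: dict  # (x, y) -> N x N mean z-matrix
    sizes: dict  # (x, y) -> observation count
    pairwise_differences: dict  # ((x1,y1),(x2,y2)) -> difference matrix
    margin_differences: dict  # e.g. "X2-X1" -> difference matrix
    node_order: np.ndarray = None
    missing: list = field(default_factory=list)


def summarize_archetypes(cs: ConnectomeSet, coords: np.ndarray) -> ArchetypeSummary:
    """Mean connectome per archetype plus pairwise and margin differences.

    ``coords`` is the (n_obs, 2) array of archetype grid coordinates (from
    the representative run). Means are computed on the Fisher-z matrices.
    Margin differences compare consecutive levels pooled over the other
    factor (e.g. ``X2-X1`` = mean over all x=2 observations minus mean over
    all x=1). When the connectome set carries a node->network map, rows and
    columns are re-ordered by network for display.
    """
    coords = np.asarray(coords)
    if coords.shape != (cs.n_obs, 2):
        raise ValueError("coords must be (n_obs, 2)")
    xs = np.unique(coords[:, 0])
    ys = np.unique(coords[:, 1])
    order = None
    mats = cs.matrices
    if cs.network_map:
        networks = np.asarray([cs.network_map.get(lab, "") for lab in cs.node_labels])
        order = np.argsort(networks, kind="stable")
        mats = mats[:, order][:, :, order]

    means, sizes, missing = {}, {}, []
    for y in ys:
        for x in xs:
            mask = (coords[:, 0] == x) & (coords[:, 1] == y)
            sizes[(int(x), int(y))] = int(mask.sum())
            if mask.any():
                means[(int(x), int(y))] = mats[mask].mean(axis=0)
            else:
                missing.append((int(x), int(y)))
                warnings.warn(f"archetype ({x}, {y}) is empty; mean undefined",
                              stacklevel=2)
    pairwise = {
        (a, b): means[b] - means[a]
        for a, b in combinations(sorted(means), 2)
    }
    margins = {}
    for j, (name, levels) in enumerate((("X", xs), ("Y", ys))):
        for lo, hi in zip(levels[:-1], levels[1:]):
            m_hi = coords[:, j] == hi
            m_lo = coords[:, j] == lo
            if m_hi.any() and m_lo.any():
                margins[f"{name}{hi}-{name}{lo}"] = (
                    mats[m_hi].mean(axis=0) - mats[m_lo].mean(axis=0)
                )
    return ArchetypeSummary(
        means=means,
        sizes=sizes,
        pairwise_differences=pairwise,
        margin_differences=margins,
        node_order=order,
        missing=missing,
    )
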