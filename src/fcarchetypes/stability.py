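"""Clustering-stability metrics and the two-step SOM fine-tuning search.

Partition agreement is measured with the Adjusted Rand Index (ARI) and
Adjusted Mutual Information (AMI), both chance-corrected so that unrelated
partitions score near zero. The fine-tuning procedure screens candidate
grid sizes at a fixed epoch count, then sweeps training epochs for the
surviving grids, averaging ARI/AMI over all pairs of repeated trainings at
each setting; the most stable (dims, epochs) combination is selected with
parsimony tie-breaks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .som import SelfOrganizingMap

__all__ = [
    "adjusted_rand_index",
    "adjusted_mutual_information",
    "pair_stability",
    "stability_search",
    "select_config",
]


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    return a, b


def _degenerate(a, b):
    """Convention for partitions without a defined chance correction.

    Single-cluster vs single-cluster compares two identical trivial
    partitions -> 1; single-cluster vs multi-cluster -> 0.
    """
    ka, kb = len(np.unique(a)), len(np.unique(b))
    if ka == 1 and kb == 1:
        return 1.0
    if ka == 1 or kb == 1:
        return 0.0
    return None


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand Index between two labelings.

    Pair-counting agreement corrected for chance under the hypergeometric
    permutation model; 1 for identical partitions, ~0 for independent ones,
    invariant to label permutation.
    """
    a, b = _check_pair(a, b)
    d = _degenerate(a, b)
    if d is not None:
        return d
    return float(adjusted_rand_score(a, b))


def adjusted_mutual_information(a, b) -> float:
    """Adjusted Mutual Information (arithmetic-mean normalization).

    ``(MI - E[MI]) / (mean(H(a), H(b)) - E[MI])`` with the expected mutual
    information taken under the permutation (hypergeometric) model.
    """
    a, b = _check_pair(a, b)
    d = _degenerate(a, b)
    if d is not None:
        return d
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def pair_stability(label_rows: np.ndarray):
    """Mean and SE of ARI/AMI over all pairs of label rows."""
    pairs = list(combinations(range(len(label_rows)), 2))
    ari = np.array([adjusted_rand_index(label_rows[i], label_rows[j]) for i, j in pairs])
    ami = np.array(
        [adjusted_mutual_information(label_rows[i], label_rows[j]) for i, j in pairs]
    )

    def se(v):
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    return {
        "ari_mean": float(ari.mean()),
        "ari_se": se(ari),
        "ami_mean": float(ami.mean()),
        "ami_se": se(ami),
        "n_pairs": len(pairs),
    }


def _repeat_labels(features, dims, epochs, n_repeats, seed_seq, **som_kwargs):
    labels = []
    for child in seed_seq.spawn(n_repeats):
        som = SelfOrganizingMap(
            dims=dims,
            epochs=epochs,
            random_state=int(child.generate_state(1)[0] % (2**31)),
            **som_kwargs,
        )
        labels.append(som.fit(features).labels_)
    return np.asarray(labels)


def stability_search(
    features,
    dims_list,
    epochs_list,
    n_repeats: int = 20,
    seed=None,
    screen_epochs: int = 100,
    n_keep_dims: int = 2,
    **som_kwargs,
) -> pd.DataFrame:
    """Two-step fine-tuning over SOM grid sizes and epoch counts.

    Step 1 screens every grid in ``dims_list`` at ``screen_epochs`` epochs;
    the ``n_keep_dims`` most stable grids survive. Step 2 sweeps
    ``epochs_list`` for the surviving grids. Each cell trains ``n_repeats``
    independently seeded SOMs and records mean/SE of ARI and AMI over all
    ``C(n_repeats, 2)`` pairs of assignments.

    Returns a DataFrame with columns ``step, dims, epochs, ari_mean,
    ari_se, ami_mean, ami_se, n_pairs, n_repeats``.
    """
    features = np.asarray(features, dtype=float)
    dims_list = list(dims_list)
    epochs_list = list(epochs_list)
    if not dims_list or not epochs_list:
        raise ValueError("dims_list and epochs_list must be non-empty")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    root = np.random.SeedSequence(seed)
    rows = []
    screen_scores = {}
    for dims in dims_list:
        labels = _repeat_labels(
            features, tuple(dims), screen_epochs, n_repeats, root.spawn(1)[0], **som_kwargs
        )
        stats = pair_stability(labels)
        screen_scores[tuple(dims)] = 0.5 * (stats["ari_mean"] + stats["ami_mean"])
        rows.append(
            {"step": 1, "dims": tuple(dims), "epochs": screen_epochs, **stats,
             "n_repeats": n_repeats}
        )
    survivors = sorted(
        screen_scores,
        key=lambda d: (-screen_scores[d], d[0] * d[1]),
    )[: max(1, n_keep_dims)]
    for dims in survivors:
        for epochs in epochs_list:
            labels = _repeat_labels(
                features, dims, epochs, n_repeats, root.spawn(1)[0], **som_kwargs
            )
            stats = pair_stability(labels)
            rows.append(
                {"step": 2, "dims": dims, "epochs": epochs, **stats,
                 "n_repeats": n_repeats}
            )
    return pd.DataFrame(rows)


def select_config(table: pd.DataFrame, rule: str = "mean_ari_ami"):
    """Pick the (dims, epochs) with the highest mean of ARI and AMI.

    Only step-2 rows are considered when a ``step`` column is present.
    Ties are broken toward fewer epochs, then the smaller grid — the
    parsimony reading of "most stable without overfitting".
    """
    if table.empty:
        raise ValueError("empty stability table")
    if rule != "mean_ari_ami":
        raise ValueError(f"unknown selection rule {rule!r}")
    t = table
    if "step" in t.columns and (t["step"] == 2).any():
        t = t[t["step"] == 2]
    score = 0.5 * (t["ari_mean"] + t["ami_mean"])
    if score.isna().all():
        raise ValueError("all stability scores are NaN")
    order = sorted(
        range(len(t)),
        key=lambda i: (
            -score.iloc[i],
            t["epochs"].iloc[i],
            t["dims"].iloc[i][0] * t["dims"].iloc[i][1],
        ),
    )
    best = t.iloc[order[0]]
    return tuple(best["dims"]), int(best["epochs"])
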