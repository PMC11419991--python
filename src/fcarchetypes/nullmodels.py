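"""Monte-Carlo null for within-subject cluster-assignment consistency.

If runs of the same subject were assigned to archetypes at random, the
expected number of distinct archetypes per subject would follow the
occupancy formula ``k * (1 - (1 - 1/k)^R)``. Comparing the observed mean
unique-archetype count against a simulated random-assignment null shows
whether a subject's connectomes are assigned more consistently than
chance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConsistencyReport",
    "NullDistribution",
    "unique_cluster_histogram",
    "random_assignment_null",
    "consistency_test",
]


def unique_cluster_histogram(labels, subject_ids):
    """Distinct-cluster count per subject.

    Returns ``(histogram, mean)`` where ``histogram`` maps a unique-count
    value to the number of subjects with that count. Subjects with zero
    runs cannot occur by construction (they would have no rows); empty
    inputs raise.
    """
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    if labels.shape != subject_ids.shape or labels.size == 0:
        raise ValueError("labels and subject_ids must be equal-length, non-empty")
    counts = []
    for s in np.unique(subject_ids):
        counts.append(len(np.unique(labels[subject_ids == s])))
    counts = np.asarray(counts)
    values, freq = np.unique(counts, return_counts=True)
    hist = {int(v): int(f) for v, f in zip(values, freq)}
    return hist, float(counts.mean())


@dataclass
class NullDistribution:
    """Random-assignment null: per-simulation mean unique-cluster counts."""

    means: np.ndarray
    n_subjects: int
    n_runs: int
    k: int
    n_sims: int
    seed: object = None

    @property
    def analytic_mean(self) -> float:
        """Occupancy expectation ``k * (1 - (1 - 1/k)^R)``."""
        return self.k * (1 - (1 - 1 / self.k) ** self.n_runs)


def random_assignment_null(
    n_subjects: int,
    n_runs: int,
    k: int,
    n_sims: int = 10_000,
    seed=None,
    chunk: int = 200_000,
    probs=None,
) -> NullDistribution:
    """Simulate random i.i.d. cluster assignment.

    Each simulation assigns every (subject, run) an independent label in
    ``1..k`` — uniform by default, or drawn with the given ``probs`` (e.g.
    the empirical cluster frequencies, useful when archetype sizes are
    unbalanced) — and records the mean unique-label count per subject.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (k,) or np.any(probs < 0):
            raise ValueError("probs must be k non-negative weights")
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    means = np.empty(n_sims)
    # chunked so n_sims * n_subjects * n_runs never materializes at once
    per = max(1, chunk // max(1, n_subjects * n_runs))
    done = 0
    while done < n_sims:
        b = min(per, n_sims - done)
        if probs is None:
            lab = rng.integers(0, k, size=(b, n_subjects, n_runs))
        else:
            lab = rng.choice(k, size=(b, n_subjects, n_runs), p=probs)
        lab.sort(axis=2)
        uniq = 1 + (np.diff(lab, axis=2) > 0).sum(axis=2)
        means[done : done + b] = uniq.mean(axis=1)
        done += b
    return NullDistribution(
        means=means, n_subjects=n_subjects, n_runs=n_runs, k=k, n_sims=n_sims,
        seed=seed,
    )


@dataclass
class ConsistencyReport:
    """Observed vs null within-subject assignment consistency."""

    histogram: dict
    observed_mean: float
    null_mean: float
    null_sd: float
    p_value: float
    n_sims: int
    n_subjects: int
    n_runs: int
    k: int
    seed: object = None

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def consistency_test(labels, subject_ids, null: NullDistribution) -> ConsistencyReport:
    """One-sided empirical test of observed consistency against the null.

    ``p = fraction of null simulations with mean unique count <= observed``
    — small p means subjects' runs are assigned to the same archetype far
    more consistently than random. When no null simulation is as low as
    the observed mean, p is reported as 0.0 (i.e. p < 1/n_sims).
    """
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    n_subj = len(np.unique(subject_ids))
    if n_subj != null.n_subjects:
        raise ValueError(
            f"observed has {n_subj} subjects but null simulated {null.n_subjects}"
        )
    _, runs_per = np.unique(subject_ids, return_counts=True)
    if not np.all(runs_per == null.n_runs):
        raise ValueError("observed runs-per-subject does not match the null")
    if labels.max() > null.k:
        raise ValueError("observed labels exceed the null's cluster count k")
    if len(np.unique(labels)) < null.k:
        warnings.warn("observed uses fewer clusters than the null's k", stacklevel=2)
    hist, obs_mean = unique_cluster_histogram(labels, subject_ids)
    p = float((null.means <= obs_mean).mean())
    return ConsistencyReport(
        histogram=hist,
        observed_mean=obs_mean,
        null_mean=float(null.means.mean()),
        null_sd=float(null.means.std(ddof=1)),
        p_value=p,
        n_sims=null.n_sims,
        n_subjects=null.n_subjects,
        n_runs=null.n_runs,
        k=null.k,
        seed=null.seed,
    )
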