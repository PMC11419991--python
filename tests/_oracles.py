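"""Independent brute-force oracles used to check the implementation.

Everything here is written directly from first principles (contingency
tables, exhaustive enumeration, naive agglomeration) and never calls the
package or scikit-learn.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb, log

import numpy as np
from scipy.stats import hypergeom


def contingency(a, b):
    la = {v: i for i, v in enumerate(sorted(set(a)))}
    lb = {v: i for i, v in enumerate(sorted(set(b)))}
    table = np.zeros((len(la), len(lb)), dtype=int)
    for x, y in zip(a, b):
        table[la[x], lb[y]] += 1
    return table


def brute_ari(a, b) -> float:
    """ARI from the pair-counting formula on the raw contingency table."""
    t = contingency(a, b)
    n = t.sum()
    index = sum(comb(int(v), 2) for v in t.ravel())
    sum_a = sum(comb(int(v), 2) for v in t.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in t.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def _mi(t) -> float:
    n = t.sum()
    ai = t.sum(axis=1)
    bj = t.sum(axis=0)
    mi = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            nij = t[i, j]
            if nij > 0:
                mi += (nij / n) * log(n * nij / (ai[i] * bj[j]))
    return mi


def _entropy(counts) -> float:
    n = counts.sum()
    return -sum((c / n) * log(c / n) for c in counts if c > 0)


def brute_emi(a, b) -> float:
    """Expected MI under the hypergeometric (fixed-marginal) model."""
    t = contingency(a, b)
    n = int(t.sum())
    ai = t.sum(axis=1)
    bj = t.sum(axis=0)
    emi = 0.0
    for x in ai:
        for y in bj:
            lo = max(0, int(x + y - n))
            hi = min(int(x), int(y))
            for nij in range(max(lo, 1), hi + 1):
                p = hypergeom.pmf(nij, n, int(x), int(y))
                emi += p * (nij / n) * log(n * nij / (x * y))
    return emi


def brute_ami(a, b) -> float:
    """AMI with arithmetic-mean normalization, from first principles."""
    t = contingency(a, b)
    mi = _mi(t)
    emi = brute_emi(a, b)
    h = 0.5 * (_entropy(t.sum(axis=1)) + _entropy(t.sum(axis=0)))
    denom = h - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


def emi_by_permutation(a, b) -> float:
    """E[MI] by exhaustively permuting one labeling (tiny n only)."""
    b = list(b)
    vals = [_mi(contingency(a, perm)) for perm in permutations(b)]
    return float(np.mean(vals))


def brute_consensus_matrix(labels) -> np.ndarray:
    labels = np.asarray(labels)
    n_runs, n_obs = labels.shape
    m = np.zeros((n_obs, n_obs))
    for i in range(n_obs):
        for j in range(n_obs):
            m[i, j] = sum(labels[r, i] == labels[r, j] for r in range(n_runs)) / n_runs
    return m


def brute_average_linkage(d: np.ndarray):
    """Naive average-linkage agglomeration.

    Returns (heights, partitions) where partitions[k] is the list of
    cluster membership frozensets when exactly k clusters remain.
    """
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    partitions = {n: list(clusters)}
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            dist = np.mean([d[p, q] for p in clusters[i] for q in clusters[j]])
            if best is None or dist < best[0] - 1e-15:
                best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
        partitions[len(clusters)] = list(clusters)
    return heights, partitions


def partition_sets(labels) -> set:
    """Partition as a set of frozensets of observation indices."""
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == v)) for v in np.unique(labels)}


def brute_unique_counts(labels, subject_ids) -> dict:
    out = {}
    for lab, s in zip(labels, subject_ids):
        out.setdefault(s, set()).add(lab)
    return {s: len(v) for s, v in out.items()}


def balanced_twoway_f(scores, x, y):
    """Hand sums-of-squares two-way ANOVA (balanced design only).

    Returns dict of term -> (F, df1, df2).
    """
    scores = np.asarray(scores, dtype=float)
    x = np.asarray(x)
    y = np.asarray(y)
    xs, ys = np.unique(x), np.unique(y)
    grand = scores.mean()
    n = len(scores)
    ss_x = sum((scores[x == xi].mean() - grand) ** 2 * (x == xi).sum() for xi in xs)
    ss_y = sum((scores[y == yi].mean() - grand) ** 2 * (y == yi).sum() for yi in ys)
    ss_cells = 0.0
    ss_err = 0.0
    for xi in xs:
        for yi in ys:
            cell = scores[(x == xi) & (y == yi)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_xy = ss_cells - ss_x - ss_y
    df_x, df_y = len(xs) - 1, len(ys) - 1
    df_xy = df_x * df_y
    df_err = n - len(xs) * len(ys)
    ms_err = ss_err / df_err
    return {
        "X": (ss_x / df_x / ms_err, df_x, df_err),
        "Y": (ss_y / df_y / ms_err, df_y, df_err),
        "X:Y": (ss_xy / df_xy / ms_err, df_xy, df_err),
    }


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values by the step-up recursion."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
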