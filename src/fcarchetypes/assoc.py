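"""Grid-coordinate brain-behavior association battery.

Behavioral scores are normalized (Box-Cox by maximum likelihood, then
min-max rescaled to 1..100) and regressed on the archetype grid
coordinates as categorical factors: X and Y main effects plus the X:Y
interaction, via two-way ANOVA (Type-II sums of squares for unbalanced
designs) and, as the multiverse twin, a linear mixed-effects model with a
random intercept per subject (guarding against pseudo-replication when
runs are stacked as observations). Post-hoc Welch comparisons are
restricted to grid-cell pairs differing in exactly one coordinate, with
Benjamini-Hochberg and Bonferroni corrections. The degeneracy report then
flags interaction-coded behaviors where connectionally distant archetypes
share the same elevated outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import inv_boxcox
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BoxCoxRecord",
    "BoxCoxRescaler",
    "boxcox_rescale",
    "inverse_boxcox_rescale",
    "preprocess_behaviors",
    "anova_grid",
    "lme_grid",
    "posthoc_pairwise",
    "correct_pvalues",
    "AssociationResult",
    "association_battery",
    "classify_coding",
    "degeneracy_report",
]

TERMS = ("X", "Y", "X:Y")


# ---------------------------------------------------------------------------
# Box-Cox + 1..100 normalization
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxRecord:
    """Parameters of one column's Box-Cox + min-max transform."""

    lmbda: float
    shift: float
    y_min: float
    y_max: float


#: Bound on the Box-Cox exponent. The unconstrained MLE diverges when a
#: score's location is much larger than its spread (the profile likelihood
#: is nearly flat in lambda and x**lambda overflows); |lambda| <= 5 covers
#: every transform of practical interest.
_LAMBDA_BOUND = 5.0


def boxcox_rescale(x, lmbda: float = None):
    """Box-Cox transform (lambda by MLE) then min-max rescale to [1, 100].

    A shift of ``1 - min(x)`` is applied first when ``min(x) <= 0`` so all
    inputs are positive; the MLE of lambda is taken over ``[-5, 5]``
    unless ``lmbda`` forces a fixed exponent. Returns
    ``(scaled, BoxCoxRecord)``.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct values for Box-Cox")
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - x.min()
    xs = x + shift
    if lmbda is None:
        opt = sps.boxcox_normmax(
            xs,
            method="mle",
            optimizer=lambda fun: optimize.minimize_scalar(
                fun, bounds=(-_LAMBDA_BOUND, _LAMBDA_BOUND), method="bounded"
            ),
        )
        lmbda = float(opt)
    y = sps.boxcox(xs, lmbda=lmbda)
    y_min, y_max = float(y.min()), float(y.max())
    scaled = 1.0 + 99.0 * ((y - y_min) / (y_max - y_min))
    return scaled, BoxCoxRecord(float(lmbda), shift, y_min, y_max)


def inverse_boxcox_rescale(scaled, record: BoxCoxRecord):
    """Invert :func:`boxcox_rescale` back to the raw scores."""
    scaled = np.asarray(scaled, dtype=float)
    y = record.y_min + (scaled - 1.0) * (record.y_max - record.y_min) / 99.0
    return inv_boxcox(y, record.lmbda) - record.shift


class BoxCoxRescaler(TransformerMixin, BaseEstimator):
    """Column-wise Box-Cox + 1..100 rescaling of a behavior table."""

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.records_ = {}
        for col in X.columns:
            _, rec = boxcox_rescale(X[col].to_numpy())
            self.records_[col] = rec
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        out = {}
        for col in X.columns:
            rec = self.records_[col]
            y = sps.boxcox(X[col].to_numpy() + rec.shift, lmbda=rec.lmbda)
            out[col] = 1.0 + 99.0 * ((y - rec.y_min) / (rec.y_max - rec.y_min))
        return pd.DataFrame(out, index=X.index)


def preprocess_behaviors(table: pd.DataFrame, id_col: str = "subject_id"):
    """Normalize every behavior column; drop rows with missing scores.

    Returns ``(transformed table, {column: BoxCoxRecord})``.
    """
    table = pd.DataFrame(table)
    cols = [c for c in table.columns if c != id_col]
    n0 = len(table)
    table = table.dropna(subset=cols)
    if len(table) < n0:
        warnings.warn(f"dropped {n0 - len(table)} row(s) with missing scores",
                      stacklevel=2)
    out = table[[id_col]].copy() if id_col in table else pd.DataFrame(index=table.index)
    records = {}
    for col in cols:
        out[col], records[col] = boxcox_rescale(table[col].to_numpy())
    return out, records


# ---------------------------------------------------------------------------
# ANOVA / LME on grid coordinates
# ---------------------------------------------------------------------------

def _grid_frame(scores, coords):
    scores = np.asarray(scores, dtype=float)
    coords = np.asarray(coords)
    if coords.shape != (len(scores), 2):
        raise ValueError("coords must be (n_obs, 2)")
    return pd.DataFrame(
        {"score": scores, "X": coords[:, 0].astype(int), "Y": coords[:, 1].astype(int)}
    )


def anova_grid(scores, coords, ss_type: int = 2) -> pd.DataFrame:
    """Two-way ANOVA of scores on grid coordinates X, Y and X:Y.

    Factors are categorical; unbalanced designs use Type-II sums of
    squares by default (Type III via ``ss_type=3``). Returns a DataFrame
    indexed by term with columns ``F, df, p``. A single-level factor makes
    its main effect (and the interaction) undefined — reported as NaN. An
    empty grid cell drops the interaction term with a warning.
    """
    df = _grid_frame(scores, coords)
    out = pd.DataFrame(index=list(TERMS), columns=["F", "df", "p"], dtype=float)
    if df["score"].var(ddof=0) == 0:
        # constant response: no variance for any term to explain
        out.loc[:, "F"] = 0.0
        out.loc[:, "p"] = 1.0
        out.loc[:, "df"] = np.nan
        return out
    nx, ny = df["X"].nunique(), df["Y"].nunique()
    terms = []
    if nx >= 2:
        terms.append("C(X)")
    if ny >= 2:
        terms.append("C(Y)")
    with_interaction = nx >= 2 and ny >= 2
    if with_interaction:
        cells = df.groupby(["X", "Y"]).size()
        if len(cells) < nx * ny:
            warnings.warn("empty grid cell: interaction term dropped", stacklevel=2)
            with_interaction = False
    if with_interaction:
        terms.append("C(X):C(Y)")
    if not terms:
        return out
    model = ols("score ~ " + " + ".join(terms), data=df).fit()
    tbl = anova_lm(model, typ=ss_type)
    rename = {"C(X)": "X", "C(Y)": "Y", "C(X):C(Y)": "X:Y"}
    for raw, term in rename.items():
        if raw in tbl.index:
            out.loc[term, "F"] = tbl.loc[raw, "F"]
            out.loc[term, "df"] = tbl.loc[raw, "df"]
            out.loc[term, "p"] = tbl.loc[raw, "PR(>F)"]
    return out


def lme_grid(scores, coords, subject_ids) -> pd.DataFrame:
    """Mixed model ``score ~ C(X) * C(Y) + (1 | subject)``, REML fit.

    Returns a DataFrame indexed by term with Wald ``stat`` (chi-square),
    ``df``, ``p`` and a ``converged`` flag. Degenerate fits (zero score
    variance, non-convergence) are flagged rather than raised so the ANOVA
    arm of the multiverse still reports.
    """
    df = _grid_frame(scores, coords)
    df["subject"] = np.asarray(subject_ids)
    out = pd.DataFrame(index=list(TERMS), columns=["stat", "df", "p"], dtype=float)
    out["converged"] = False
    if df["score"].var(ddof=0) == 0:
        warnings.warn("zero-variance scores: mixed model degenerate", stacklevel=2)
        return out
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = mixedlm("score ~ C(X) * C(Y)", data=df, groups=df["subject"])
            res = model.fit(reml=True)
        if res.scale <= 1e-10 * df["score"].var(ddof=0):
            # scores constant within subject: the random intercept fits every
            # subject exactly and fixed effects are unidentified
            warnings.warn(
                "no residual (within-subject) score variance: mixed model "
                "degenerate; use a subject-level analysis instead",
                stacklevel=2,
            )
            return out
        design_info = res.model.data.design_info
        k_fe = len(res.fe_params)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        rename = {"C(X)": "X", "C(Y)": "Y", "C(X):C(Y)": "X:Y"}
        for raw, term in rename.items():
            if raw not in design_info.term_names:
                continue
            sl = design_info.slice(raw)
            b = np.asarray(res.fe_params)[sl]
            vb = cov[sl, sl]
            stat = float(b @ np.linalg.solve(vb, b))
            dof = len(b)
            out.loc[term, ["stat", "df", "p"]] = (
                stat, dof, float(sps.chi2.sf(stat, dof)),
            )
        out["converged"] = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"mixed model failed: {err}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Post-hoc comparisons and corrections
# ---------------------------------------------------------------------------

def correct_pvalues(p_list, method: str = "fdr_bh") -> np.ndarray:
    """Adjust p-values: Benjamini-Hochberg step-up or Bonferroni."""
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=method)[1]


def posthoc_pairwise(scores, coords, restriction: str = "one_coordinate") -> pd.DataFrame:
    """Welch t-tests between grid cells, corrected within the behavior.

    ``restriction="one_coordinate"`` keeps only cell pairs differing in
    exactly one coordinate (on a 2x2 grid: 4 of the 6 pairs — the
    cross-diagonal pairs enter only through the interaction term);
    ``"all_pairs"`` keeps every pair. Cells with fewer than 2 observations
    are skipped with a warning. Raw p-values receive both FDR (BH) and
    Bonferroni corrections over the retained family.
    """
    if restriction not in ("one_coordinate", "all_pairs"):
        raise ValueError(f"unknown restriction {restriction!r}")
    df = _grid_frame(scores, coords)
    cells = {}
    for (x, y), grp in df.groupby(["X", "Y"]):
        cells[(int(x), int(y))] = grp["score"].to_numpy()
    rows = []
    for a, b in combinations(sorted(cells), 2):
        n_diff = int(a[0] != b[0]) + int(a[1] != b[1])
        if restriction == "one_coordinate" and n_diff != 1:
            continue
        ga, gb = cells[a], cells[b]
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(f"cell pair {a} vs {b} skipped (<2 observations)",
                          stacklevel=2)
            continue
        t = sps.ttest_ind(ga, gb, equal_var=False)
        rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "mean_diff": float(ga.mean() - gb.mean()),
                "t": float(t.statistic),
                "df": float(t.df),
                "p_raw": float(t.pvalue),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_fdr"] = correct_pvalues(table["p_raw"], "fdr_bh")
        table["p_bonf"] = correct_pvalues(table["p_raw"], "bonferroni")
    return table


# ---------------------------------------------------------------------------
# Battery, tier map, classification, degeneracy
# ---------------------------------------------------------------------------

def _modal_coords(coords, subject_ids):
    """One (subject, modal grid cell) pair per subject; ties to the
    lexicographically lowest cell."""
    coords = np.asarray(coords)
    subject_ids = np.asarray(subject_ids)
    subjects = pd.unique(subject_ids)
    modal = np.empty((len(subjects), 2), dtype=int)
    for i, s in enumerate(subjects):
        rows = coords[subject_ids == s]
        cells, counts = np.unique(rows, axis=0, return_counts=True)
        modal[i] = cells[np.lexsort((cells[:, 1], cells[:, 0], -counts))[0]]
    return subjects, modal


@dataclass
class AssociationResult:
    """All association outputs for a behavior battery."""

    anova: pd.DataFrame  # long form: behavior, term, F, df, p
    lme: pd.DataFrame  # long form: behavior, term, stat, df, p, converged
    posthoc: dict  # behavior -> posthoc table
    tiers: pd.DataFrame  # behavior, term, p, p_fdr, p_bonf, tier flags
    scores: pd.DataFrame = field(default=None, repr=False)
    coords: np.ndarray = field(default=None, repr=False)
    subject_ids: np.ndarray = field(default=None, repr=False)


def _tier_map(anova_long: pd.DataFrame, alpha: float = 0.05,
              p_uncorrected: float = 1e-3) -> pd.DataFrame:
    """Significance tiers across the behaviors x terms family.

    Mirrors a tier heatmap: ``uncorrected`` marks raw p below ``1e-3``,
    ``fdr``/``bonferroni`` mark survival of the respective correction over
    the whole family at ``alpha``.
    """
    t = anova_long.dropna(subset=["p"]).copy()
    if t.empty:
        return t
    t["p_fdr"] = correct_pvalues(t["p"], "fdr_bh")
    t["p_bonf"] = correct_pvalues(t["p"], "bonferroni")
    t["sig_uncorrected"] = t["p"] < p_uncorrected
    t["sig_fdr"] = t["p_fdr"] < alpha
    t["sig_bonferroni"] = t["p_bonf"] < alpha
    return t


def association_battery(
    behaviors: pd.DataFrame,
    coords: np.ndarray,
    subject_ids,
    id_col: str = "subject_id",
    restriction: str = "one_coordinate",
    ss_type: int = 2,
    use_lme: bool = True,
    alpha: float = 0.05,
    p_uncorrected: float = 1e-3,
    level: str = "observation",
) -> AssociationResult:
    """Run the full battery for every behavior column.

    ``behaviors`` holds one row per subject. With ``level="observation"``
    (default) scores are replicated across that subject's observations to
    align with the per-run ``coords`` (a trait is constant over runs): the
    ANOVA treats every connectome as an observation and the mixed model
    adds a random intercept per subject as the statistically guarded twin
    of the multiverse. With ``level="subject"`` each subject enters once,
    at their modal (most frequent, ties to the lowest cell) coordinate,
    and the mixed-model arm is skipped as redundant.
    """
    coords = np.asarray(coords)
    subject_ids = np.asarray(subject_ids)
    if level not in ("observation", "subject"):
        raise ValueError(f"unknown level {level!r}")
    if level == "subject":
        subjects, coords = _modal_coords(coords, subject_ids)
        subject_ids = subjects
        use_lme = False
    beh = behaviors.set_index(id_col)
    missing = set(subject_ids) - set(beh.index)
    if missing:
        raise ValueError(f"behavior table missing subjects: {sorted(missing)[:5]} ...")
    aligned = beh.loc[subject_ids]
    anova_rows, lme_rows, posthoc = [], [], {}
    for col in beh.columns:
        scores = aligned[col].to_numpy()
        a = anova_grid(scores, coords, ss_type=ss_type)
        for term, row in a.iterrows():
            anova_rows.append({"behavior": col, "term": term, **row.to_dict()})
        if use_lme:
            l = lme_grid(scores, coords, subject_ids)
            for term, row in l.iterrows():
                lme_rows.append({"behavior": col, "term": term, **row.to_dict()})
        posthoc[col] = posthoc_pairwise(scores, coords, restriction=restriction)
    anova_long = pd.DataFrame(anova_rows)
    lme_long = pd.DataFrame(lme_rows)
    tiers = _tier_map(anova_long, alpha=alpha, p_uncorrected=p_uncorrected)
    return AssociationResult(
        anova=anova_long,
        lme=lme_long,
        posthoc=posthoc,
        tiers=tiers,
        scores=aligned.reset_index(),
        coords=coords,
        subject_ids=subject_ids,
    )


def classify_coding(result: AssociationResult, tier: str = "bonferroni") -> dict:
    """Classify each behavior by its most significant surviving term.

    ``tier`` selects which significance tier a term must survive
    (``"uncorrected"``: raw p below 1e-3; ``"fdr"``; ``"bonferroni"``).
    Returns ``{behavior: "X-coded" | "Y-coded" | "interaction-coded" |
    "uncoded"}``.
    """
    flag = {
        "uncorrected": "sig_uncorrected",
        "fdr": "sig_fdr",
        "bonferroni": "sig_bonferroni",
    }.get(tier)
    if flag is None:
        raise ValueError(f"unknown tier {tier!r}")
    naming = {"X": "X-coded", "Y": "Y-coded", "X:Y": "interaction-coded"}
    out = {}
    for beh, grp in result.tiers.groupby("behavior"):
        surviving = grp[grp[flag]]
        if surviving.empty:
            out[beh] = "uncoded"
        else:
            best = surviving.loc[surviving["p"].idxmin()]
            out[beh] = naming[best["term"]]
    for beh in result.scores.columns:
        if beh != "subject_id":
            out.setdefault(beh, "uncoded")
    return out


def _archetype_distances(summary) -> dict:
    from .features import vectorize_lower_triangle

    vecs = {cell: vectorize_lower_triangle(m) for cell, m in summary.means.items()}
    return {
        (a, b): float(np.linalg.norm(vecs[a] - vecs[b]))
        for a, b in combinations(sorted(vecs), 2)
    }


def degeneracy_report(
    result: AssociationResult,
    summary=None,
    tier: str = "bonferroni",
    equivalence_alpha: float = 0.05,
    direction: str = "high",
) -> dict:
    """Per-behavior coding classification plus degenerate archetype pairs.

    A degenerate pair, for an interaction-coded behavior, is two
    archetypes whose behavioral cell means are statistically
    indistinguishable (Welch p >= ``equivalence_alpha``, uncorrected)
    while their mean connectomes are at least as far apart as the median
    pairwise archetype distance — structurally different profiles, same
    behavioral outcome. With ``direction="high"`` (default) only pairs
    sharing an *elevated* outcome (pooled mean above the behavior's grand
    mean) are reported, matching the degeneracy phenomenon of interest;
    ``direction="both"`` also reports pairs sharing a low outcome. When no
    archetype summary is available the connectivity-distance criterion is
    skipped and flagged.
    """
    if direction not in ("high", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    coding = classify_coding(result, tier=tier)
    distances = None
    median_distance = None
    if summary is not None and summary.means:
        distances = _archetype_distances(summary)
        median_distance = float(np.median(list(distances.values())))
    report = {"tier": tier, "median_archetype_distance": median_distance,
              "behaviors": {}}
    coords = result.coords
    for beh, cls in coding.items():
        entry = {"coding": cls, "degenerate_pairs": []}
        if cls == "interaction-coded":
            scores = result.scores[beh].to_numpy()
            grand = scores.mean()
            cells = {}
            for cell in {(int(cx), int(cy)) for cx, cy in coords}:
                mask = (coords[:, 0] == cell[0]) & (coords[:, 1] == cell[1])
                cells[cell] = scores[mask]
            for a, b in combinations(sorted(cells), 2):
                ga, gb = cells[a], cells[b]
                if len(ga) < 2 or len(gb) < 2:
                    continue
                p_eq = float(sps.ttest_ind(ga, gb, equal_var=False).pvalue)
                if p_eq < equivalence_alpha:
                    continue
                pooled_mean = float(np.concatenate([ga, gb]).mean())
                if direction == "high" and pooled_mean <= grand:
                    continue
                pair = {
                    "cells": [list(a), list(b)],
                    "equivalence_p": p_eq,
                    "pooled_mean": pooled_mean,
                    "connectome_distance": None,
                }
                if distances is not None:
                    dist = distances.get((a, b), distances.get((b, a)))
                    if dist is None or dist < median_distance:
                        continue
                    pair["connectome_distance"] = dist
                else:
                    pair["connectivity_criterion"] = "skipped: no archetype summary"
                entry["degenerate_pairs"].append(pair)
        report["behaviors"][beh] = entry
    return report
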