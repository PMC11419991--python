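import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcarchetypes import (
    GroundTruth,
    anova_grid,
    association_battery,
    boxcox_rescale,
    classify_coding,
    correct_pvalues,
    degeneracy_report,
    inverse_boxcox_rescale,
    lme_grid,
    posthoc_pairwise,
    preprocess_behaviors,
    simulate_behavior,
)
from fcarchetypes.consensus import ArchetypeSummary

from _oracles import balanced_twoway_f, bh_stepup


class TestBoxCox:
    def test_forced_identity_lambda_is_affine(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(5, 20, 100)
        scaled, rec = boxcox_rescale(x, lmbda=1.0)
        # affine transform then min-max == min-max of the raw scores
        raw_scaled = 1 + 99 * (x - x.min()) / (x.max() - x.min())
        np.testing.assert_allclose(scaled, raw_scaled, atol=1e-9)
        assert rec.lmbda == 1.0

    def test_lognormal_mle_lambda_near_zero(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.standard_normal(5000))
        _, rec = boxcox_rescale(x)
        assert abs(rec.lmbda) < 0.1

    def test_output_range_exact(self):
        rng = np.random.default_rng(2)
        scaled, _ = boxcox_rescale(rng.gamma(2.0, 1.0, 500))
        assert scaled.min() == 1.0
        assert scaled.max() == 100.0

    def test_round_trip_recovers_raw_scores(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-2.0, 1.5, 300)  # forces a positivity shift
        scaled, rec = boxcox_rescale(x)
        assert rec.shift > 0
        np.testing.assert_allclose(inverse_boxcox_rescale(scaled, rec), x, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            boxcox_rescale(np.ones(10))
        with pytest.raises(ValueError):
            boxcox_rescale(np.array([1.0, 2.0, 1.0, 2.0]))

    def test_preprocess_drops_missing_rows(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(30)],
                "a": rng.gamma(2, 1, 30),
                "b": rng.gamma(2, 1, 30),
            }
        )
        table.loc[3, "a"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            out, records = preprocess_behaviors(table)
        assert len(out) == 29
        assert set(records) == {"a", "b"}


class TestAnovaGrid:
    def test_balanced_interaction_matches_hand_sums_of_squares(self):
        # cells (X,Y): scores per cell [(1,2),(1,2),(1,2),(5,6)]
        scores = np.array([1, 2, 1, 2, 1, 2, 5, 6], dtype=float)
        x = np.array([1, 1, 2, 2, 1, 1, 2, 2])
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        got = anova_grid(scores, np.stack([x, y], axis=1))
        expected = balanced_twoway_f(scores, x, y)
        for term in ("X", "Y", "X:Y"):
            assert got.loc[term, "F"] == pytest.approx(expected[term][0], rel=1e-10)

    def test_constant_scores_give_zero_f(self):
        coords = np.array([[1, 1], [2, 1], [1, 2], [2, 2]] * 3)
        got = anova_grid(np.full(12, 7.0), coords)
        assert (got["F"] == 0).all()
        assert (got["p"] == 1).all()

    def test_pure_x_shift_detected_only_on_x(self):
        rng = np.random.default_rng(4)
        coords = np.stack(
            [rng.integers(1, 3, 400), rng.integers(1, 3, 400)], axis=1
        )
        scores = (coords[:, 0] == 2) * 1.0 + rng.normal(0, 1e-6, 400)
        got = anova_grid(scores, coords)
        assert got.loc["X", "p"] < 1e-10
        assert got.loc["Y", "p"] > 1e-10
        assert got.loc["X:Y", "p"] > 1e-10

    def test_single_level_factor_reported_missing(self):
        coords = np.array([[1, 1], [1, 2]] * 10)
        scores = np.arange(20, dtype=float)
        got = anova_grid(scores, coords)
        assert np.isnan(got.loc["X", "F"])
        assert np.isfinite(got.loc["Y", "F"])

    def test_empty_cell_drops_interaction(self):
        coords = np.array([[1, 1], [2, 1], [1, 2]] * 5)
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="empty grid cell"):
            got = anova_grid(rng.standard_normal(15), coords)
        assert np.isnan(got.loc["X:Y", "F"])


class TestLmeGrid:
    def test_single_run_per_subject_tracks_anova(self):
        rng = np.random.default_rng(6)
        n = 200
        coords = np.stack([rng.integers(1, 3, n), rng.integers(1, 3, n)], axis=1)
        scores = (coords[:, 0] == 2) * 0.8 + rng.standard_normal(n)
        subjects = np.arange(n).astype(str)
        a = anova_grid(scores, coords)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            l = lme_grid(scores, coords, subjects)
        assert l["converged"].all()
        # same significance ordering on the planted X effect
        assert l.loc["X", "p"] < 1e-4 and a.loc["X", "p"] < 1e-4
        assert l.loc["Y", "p"] > 0.01 and l.loc["X:Y", "p"] > 0.01

    def test_lme_guards_against_pseudoreplication(self):
        # strong subject intercepts + replicated runs: the naive ANOVA
        # inflates type-I error on null terms, the mixed model does not
        rng = np.random.default_rng(7)
        n_sub, n_run, reps = 40, 4, 200
        lme_rej = anova_rej = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(reps):
                subj = np.repeat(np.arange(n_sub), n_run)
                # runs share the subject's modal cell with probability 0.8,
                # so the grid regressors are cluster-correlated (as in real
                # multi-run data) and naive OLS standard errors shrink
                modal = rng.integers(1, 3, size=(n_sub, 2))
                coords = np.repeat(modal, n_run, axis=0)
                resample = rng.random(n_sub * n_run) > 0.8
                coords[resample] = rng.integers(
                    1, 3, size=(int(resample.sum()), 2)
                )
                score = np.repeat(rng.standard_normal(n_sub) * 2, n_run)
                score = score + rng.standard_normal(n_sub * n_run)
                anova_rej += anova_grid(score, coords).loc["X", "p"] < 0.05
                lme_rej += lme_grid(score, coords, subj).loc["X", "p"] < 0.05
        assert lme_rej / reps <= 1.5 * 0.05 + 0.04  # ~nominal + binomial slack
        assert anova_rej / reps > 1.5 * 0.05
        assert anova_rej > lme_rej

    def test_constant_scores_flagged(self):
        coords = np.array([[1, 1], [2, 1], [1, 2], [2, 2]] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            out = lme_grid(np.full(20, 3.0), coords, np.arange(20) // 2)
        assert not out["converged"].any()
        assert out["p"].isna().all()

    def test_within_subject_constant_scores_flagged(self):
        rng = np.random.default_rng(8)
        subj = np.repeat(np.arange(30), 4)
        coords = np.stack([rng.integers(1, 3, 120), rng.integers(1, 3, 120)], axis=1)
        score = np.repeat(rng.standard_normal(30), 4)  # trait replicated exactly
        with pytest.warns(UserWarning, match="within-subject"):
            out = lme_grid(score, coords, subj)
        assert not out["converged"].any()


class TestPosthoc:
    @staticmethod
    def xor_data(n_per_cell=60, noise=0.3, seed=9):
        rng = np.random.default_rng(seed)
        cells = [(1, 1), (2, 1), (1, 2), (2, 2)]
        coords = np.repeat(cells, n_per_cell, axis=0)
        high = (coords[:, 0] == 2) ^ (coords[:, 1] == 2)
        scores = high * 1.0 + rng.normal(0, noise, len(coords))
        return scores, coords

    def test_restricted_family_has_four_pairs_on_2x2(self):
        scores, coords = self.xor_data()
        table = posthoc_pairwise(scores, coords)
        assert len(table) == 4
        for _, row in table.iterrows():
            diff = sum(a != b for a, b in zip(row["cell_a"], row["cell_b"]))
            assert diff == 1

    def test_all_pairs_mode_has_six(self):
        scores, coords = self.xor_data()
        assert len(posthoc_pairwise(scores, coords, restriction="all_pairs")) == 6

    def test_identical_cells_not_significant(self):
        rng = np.random.default_rng(10)
        coords = np.repeat([(1, 1), (2, 1), (1, 2), (2, 2)], 100, axis=0)
        table = posthoc_pairwise(rng.standard_normal(400), coords)
        assert (table["p_bonf"] > 0.05).all()

    def test_xor_pattern_alternates_sign_and_survives_bonferroni(self):
        scores, coords = self.xor_data()
        table = posthoc_pairwise(scores, coords)
        assert (table["p_bonf"] < 1e-6).all()
        # each restricted comparison crosses the XOR boundary once
        signs = np.sign(table["mean_diff"].to_numpy())
        assert set(signs) == {-1.0, 1.0}
        assert np.sum(signs) == 0

    def test_small_cell_skipped(self):
        coords = np.array([[1, 1], [1, 1], [2, 1]])
        with pytest.warns(UserWarning, match="skipped"):
            table = posthoc_pairwise(np.array([1.0, 2.0, 3.0]), coords)
        assert table.empty


class TestCorrections:
    def test_bh_printed_example(self):
        np.testing.assert_allclose(
            correct_pvalues([0.01, 0.02, 0.03, 0.04], "fdr_bh"),
            [0.04, 0.04, 0.04, 0.04],
            atol=1e-12,
        )

    def test_bonferroni_caps_at_one(self):
        np.testing.assert_allclose(
            correct_pvalues([0.3, 0.01, 0.5, 0.2], "bonferroni"),
            [1.0, 0.04, 1.0, 0.8],
            atol=1e-12,
        )

    def test_single_p_unchanged_by_bh(self):
        assert correct_pvalues([0.037], "fdr_bh")[0] == pytest.approx(0.037)
        assert correct_pvalues([0.037], "bonferroni")[0] == pytest.approx(0.037)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            correct_pvalues([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_dominance_and_bh_oracle(self, ps):
        bh = correct_pvalues(ps, "fdr_bh")
        bonf = correct_pvalues(ps, "bonferroni")
        assert np.all(bh >= np.asarray(ps) - 1e-15)
        assert np.all(bonf >= bh - 1e-12)
        np.testing.assert_allclose(bh, bh_stepup(ps), atol=1e-12)


def planted_battery(coding="interaction", n=240, d=0.8, seed=0, use_lme=False):
    rng = np.random.default_rng(seed)
    modal_flat = rng.integers(0, 4, n)
    modal = np.stack([1 + modal_flat % 2, 1 + modal_flat // 2], axis=1)
    subjects = np.array([f"s{i:03d}" for i in range(n)])
    truth = GroundTruth(
        archetype_per_obs=modal,
        subject_modal_archetype=modal,
        grid_dims=(2, 2),
        subject_ids=subjects,
        run_ids=np.ones(n, dtype=int),
    )
    beh = simulate_behavior(
        truth,
        effect_size=d,
        coding_map={"trait": coding, "filler": "null"},
        seed=seed + 1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = association_battery(beh, modal, subjects, use_lme=use_lme)
    return result


def template_summary(block_effect=0.75):
    from fcarchetypes import SynthConfig, generate_templates

    cfg = SynthConfig(n_nodes=30, block_effect=block_effect)
    t = generate_templates(cfg)
    means = {
        (x, y): t[x - 1, y - 1] for x in (1, 2) for y in (1, 2)
    }
    return ArchetypeSummary(
        means=means, sizes={k: 1 for k in means}, pairwise_differences={},
        margin_differences={},
    )


class TestDegeneracyReport:
    def test_planted_xor_yields_exactly_the_high_pair(self):
        result = planted_battery("interaction")
        report = degeneracy_report(result, template_summary(), tier="bonferroni")
        entry = report["behaviors"]["trait"]
        assert entry["coding"] == "interaction-coded"
        pairs = [set(map(tuple, p["cells"])) for p in entry["degenerate_pairs"]]
        assert pairs == [{(2, 1), (1, 2)}]

    def test_direction_both_adds_low_pair(self):
        result = planted_battery("interaction")
        report = degeneracy_report(
            result, template_summary(), tier="bonferroni", direction="both"
        )
        pairs = [
            set(map(tuple, p["cells"]))
            for p in report["behaviors"]["trait"]["degenerate_pairs"]
        ]
        assert {(1, 1), (2, 2)} in pairs and {(2, 1), (1, 2)} in pairs

    def test_null_behavior_is_uncoded(self):
        result = planted_battery("null")
        report = degeneracy_report(result, template_summary())
        assert report["behaviors"]["trait"]["coding"] == "uncoded"
        assert report["behaviors"]["trait"]["degenerate_pairs"] == []

    def test_x_coded_behavior_has_no_degenerate_pairs(self):
        result = planted_battery("x")
        report = degeneracy_report(result, template_summary())
        assert report["behaviors"]["trait"]["coding"] == "X-coded"
        assert report["behaviors"]["trait"]["degenerate_pairs"] == []

    def test_classification_tiers(self):
        result = planted_battery("x")
        for tier in ("uncorrected", "fdr", "bonferroni"):
            assert classify_coding(result, tier=tier)["trait"] == "X-coded"
        with pytest.raises(ValueError):
            classify_coding(result, tier="nope")

    def test_adjusted_p_dominance_in_tier_map(self):
        result = planted_battery("y")
        t = result.tiers
        assert (t["p_fdr"] >= t["p"] - 1e-15).all()
        assert (t["p_bonf"] >= t["p_fdr"] - 1e-12).all()


class TestBatteryModes:
    def test_subject_level_uses_modal_coordinates(self):
        subjects = np.repeat(["a", "b"], 4)
        coords = np.array(
            [[1, 1], [1, 1], [1, 1], [2, 2], [2, 2], [2, 2], [2, 2], [1, 2]]
        )
        from fcarchetypes.assoc import _modal_coords

        subj, modal = _modal_coords(coords, subjects)
        assert subj.tolist() == ["a", "b"]
        assert modal.tolist() == [[1, 1], [2, 2]]

    def test_missing_subject_rejected(self):
        beh = pd.DataFrame({"subject_id": ["a"], "t": [1.0]})
        with pytest.raises(ValueError, match="missing subjects"):
            association_battery(beh, np.array([[1, 1], [2, 1]]), np.array(["a", "b"]))
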