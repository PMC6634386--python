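"""Behavioral arm: RT transform, screening rules, mixed models, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilgca.behavioral import (
    AccuracyModel,
    ReactionTimeModel,
    ScreeningRules,
    apply_screening,
    bic_bayes_factor,
    refit_without_outliers,
    transform_rt,
)
from pupilgca.design import BehaviorParams, DesignSpec
from pupilgca.simulate import behavior_truth_neg_inv_rt, simulate_behavior


class TestTransformRt:
    @pytest.mark.parametrize("rt, expected", [(1000.0, -1.0), (500.0, -2.0), (250.0, -4.0)])
    def test_known_values(self, rt, expected):
        assert transform_rt(rt) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            transform_rt(0.0)
        with pytest.raises(ValueError):
            transform_rt(np.array([500.0, -1.0]))

    @given(st.floats(min_value=1.0, max_value=1e5), st.floats(min_value=1.0, max_value=1e5))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing(self, a, b):
        if a < b:
            assert transform_rt(a) < transform_rt(b)
        elif a > b:
            assert transform_rt(a) > transform_rt(b)


def records(rows):
    return pd.DataFrame(
        rows, columns=["participant", "item", "sem_type", "strength", "rt_ms", "accuracy"]
    )


def bulk(participant, item, n_correct, n_wrong, sem_type="taxonomic", strength="high", rt=800.0):
    rows = []
    for i in range(n_correct):
        rows.append((participant, item, sem_type, strength, rt, 1))
    for i in range(n_wrong):
        rows.append((participant, item, sem_type, strength, rt, 0))
    return rows


class TestScreening:
    def test_participant_below_75_percent_excluded(self):
        rows = bulk(0, 0, 74, 26) + bulk(1, 0, 80, 20)
        res = apply_screening(records(rows))
        assert res.participants_excluded == [0]
        assert res.trials_dropped_participant_screen == 100

    def test_participant_at_exactly_75_percent_retained(self):
        rows = bulk(0, 0, 75, 25) + bulk(1, 0, 80, 20)
        res = apply_screening(records(rows))
        assert res.participants_excluded == []

    def test_item_at_exactly_60_percent_retained(self):
        rows = bulk(0, 0, 60, 40) + bulk(0, 1, 90, 10) + bulk(1, 0, 60, 40) + bulk(1, 1, 90, 10)
        res = apply_screening(records(rows))
        assert res.items_excluded == []
        rows_bad = bulk(0, 0, 59, 41) + bulk(0, 1, 95, 5) + bulk(1, 0, 59, 41) + bulk(1, 1, 95, 5)
        res2 = apply_screening(records(rows_bad))
        assert res2.items_excluded == [0]

    def test_fast_correct_trials_dropped_from_rt_only(self):
        rows = bulk(0, 0, 9, 1) + [(0, 0, "taxonomic", "high", 240.0, 1)]
        res = apply_screening(records(rows))
        assert res.fast_trials_dropped_rt == 1
        assert (res.rt_records.rt_ms >= 250).all()
        # the accuracy analysis keeps both the fast trial and the error trial
        assert len(res.accuracy_records) == 11

    def test_errors_kept_in_accuracy_dropped_from_rt(self):
        rows = bulk(0, 0, 8, 2)
        res = apply_screening(records(rows))
        assert res.error_trials_dropped_rt == 2
        assert (res.rt_records.accuracy == 1).all()
        assert (res.accuracy_records.accuracy == 0).sum() == 2

    def test_removal_counts_are_disjoint_and_sum(self):
        rows = (
            bulk(0, 0, 74, 26)          # participant screen
            + bulk(1, 1, 55, 45)        # item screen (after participant 0 gone)
            + bulk(1, 2, 95, 5)
            + bulk(1, 3, 95, 5)
            + [(1, 3, "thematic", "low", 100.0, 1)]
        )
        res = apply_screening(records(rows))
        total_dropped_from_rt = (
            res.trials_dropped_participant_screen
            + res.trials_dropped_item_screen
            + res.error_trials_dropped_rt
            + res.fast_trials_dropped_rt
        )
        assert total_dropped_from_rt == res.n_trials_in - len(res.rt_records)

    def test_empty_surviving_set_rejected(self):
        rows = bulk(0, 0, 50, 50)  # participant at 50% -> everything gone
        with pytest.raises(RuntimeError):
            apply_screening(records(rows))

    def test_transformed_column_present(self):
        res = apply_screening(records(bulk(0, 0, 9, 1) + bulk(1, 1, 9, 1)))
        np.testing.assert_allclose(res.rt_records.neg_inv_rt, -1000.0 / res.rt_records.rt_ms)


class TestBayesFactor:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0.0, 1.0), (2.0, np.e), (9.2103, 100.0)],
    )
    def test_closed_form(self, delta, expected):
        assert bic_bayes_factor(100.0, 100.0 + delta) == pytest.approx(expected, rel=1e-3)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, derandomize=True)
    def test_reciprocity(self, a, b):
        assert bic_bayes_factor(a, b) * bic_bayes_factor(b, a) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def screened_rt():
    spec = DesignSpec(n_participants=14, n_items_per_cell=8, n_fillers=0, seed=31)
    beh = simulate_behavior(spec, np.random.default_rng(31))
    return spec, apply_screening(beh)


class TestReactionTimeModel:
    def test_four_coefficients_and_recovery(self, screened_rt):
        spec, scr = screened_rt
        model = ReactionTimeModel().fit(scr.rt_records)
        assert list(model.fit_.params.index) == ["Intercept", "type", "strength", "type:strength"]
        truth = behavior_truth_neg_inv_rt(spec, n_mc=100_000, seed=1)
        for term in ("type", "strength"):
            est, se = model.fit_.estimate(term), model.fit_.se(term)
            assert abs(est - truth[term]) < 3 * se, term

    def test_degenerate_data_exact(self):
        """No noise, no random effects: coefficients equal the cell algebra."""
        rows = []
        cells = {
            ("taxonomic", "high"): -0.80, ("taxonomic", "low"): -0.70,
            ("thematic", "high"): -0.90, ("thematic", "low"): -0.85,
        }
        for p in range(4):
            for i, ((ty, stg), v) in enumerate(cells.items()):
                for rep in range(3):
                    rows.append((p, i, ty, stg, -1000.0 / v, 1))
        df = records(rows)
        df["neg_inv_rt"] = transform_rt(df.rt_ms.to_numpy())
        model = ReactionTimeModel().fit(df)
        m = np.array(list(cells.values()))
        # sum-coded algebra: intercept = grand mean; effects = half differences
        assert model.fit_.estimate("Intercept") == pytest.approx(m.mean(), abs=1e-6)
        expected_type = (m[0] + m[1] - m[2] - m[3]) / 4
        assert model.fit_.estimate("type") == pytest.approx(expected_type, abs=1e-6)

    def test_outlier_refit_shrinks_bias(self, screened_rt):
        spec, scr = screened_rt
        df = scr.rt_records.copy().reset_index(drop=True)
        truth = behavior_truth_neg_inv_rt(spec, n_mc=100_000, seed=1)
        # inject one gross outlier into a single taxonomic-high trial
        idx = df.index[(df.sem_type == "taxonomic") & (df.strength == "high")][0]
        df.loc[idx, "neg_inv_rt"] = df.neg_inv_rt.mean() + 10 * df.neg_inv_rt.std()
        model = ReactionTimeModel().fit(df)
        assert model.outlier_fraction_ > 0
        bias_before = abs(model.initial_fit_.estimate("type") - truth["type"])
        bias_after = abs(model.fit_.estimate("type") - truth["type"])
        assert bias_after <= bias_before

    def test_no_outliers_means_no_refit_change(self):
        rows = []
        rng = np.random.default_rng(0)
        for p in range(6):
            for i in range(8):
                ty = "taxonomic" if i < 4 else "thematic"
                stg = "high" if i % 2 == 0 else "low"
                rows.append((p, i, ty, stg, float(800 + 40 * rng.uniform()), 1))
        df = records(rows)
        df["neg_inv_rt"] = transform_rt(df.rt_ms.to_numpy())
        model = ReactionTimeModel().fit(df)
        # uniform noise has no 3 SD outliers, so the refit is the initial fit
        assert model.outlier_fraction_ == 0.0
        pd.testing.assert_frame_equal(model.fit_.params, model.initial_fit_.params)

    def test_interaction_comparison_uses_ml_and_favors_true_model(self, screened_rt):
        _, scr = screened_rt
        model = ReactionTimeModel().fit(scr.rt_records)
        cmp_ = model.interaction_comparison()
        # the generator has no interaction, so the reduced model should win
        assert cmp_.bf_ab > 1.0
        assert cmp_.bf_ab == pytest.approx(
            np.exp((cmp_.model_b_bic - cmp_.model_a_bic) / 2)
        )


class TestAccuracyModel:
    def test_fit_and_comparison(self):
        spec = DesignSpec(n_participants=14, n_items_per_cell=8, n_fillers=0, seed=41)
        beh = simulate_behavior(spec, np.random.default_rng(41))
        scr = apply_screening(beh)
        model = AccuracyModel().fit(scr.accuracy_records)
        assert list(model.fit_.params.index) == ["Intercept", "type", "strength", "type:strength"]
        assert (model.fit_.params["se"] > 0).all()
        cmp_ = model.comparison(reduced_terms=("strength",))
        assert cmp_.bf_ab * bic_bayes_factor(cmp_.model_b_bic, cmp_.model_a_bic) == pytest.approx(1.0)


class TestRefitWithoutOutliers:
    def test_single_pass_by_construction(self):
        """Tight data + one gross outlier: the second pass removes nothing."""
        from pupilgca.behavioral import _coded_records
        from pupilgca.lmm import fit_lmm

        rng = np.random.default_rng(7)
        rows = []
        for p in range(6):
            for i in range(8):
                ty = "taxonomic" if i < 4 else "thematic"
                stg = "high" if i % 2 == 0 else "low"
                rows.append((p, i, ty, stg, float(800 + 10 * rng.uniform()), 1))
        df = records(rows)
        df["neg_inv_rt"] = transform_rt(df.rt_ms.to_numpy())
        df.loc[0, "neg_inv_rt"] += 1.0  # gross outlier against ~0.015-wide noise
        df = _coded_records(df)
        spec = ReactionTimeModel()._spec(reml=True)
        fit = fit_lmm(df, spec)
        refit, frac = refit_without_outliers(fit, df, spec, k=3.0)
        assert frac == pytest.approx(1 / len(df))
        survivors = df.drop(index=0)
        _, frac2 = refit_without_outliers(refit, survivors, spec, k=3.0)
        assert frac2 == 0.0
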