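import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import simulate_cell
from oracles import textbook_paired_t
from rlcross.stats import (
    DesignError,
    build_cohort_table,
    cell_paired_t,
    engagement_check,
    learning_curve,
    paired_t,
    plateau_accuracy,
    rm_anova_2x2,
    session_order_anova,
)


def _cell(choices, condition="gain", pair="p1"):
    n = len(choices)
    return pd.DataFrame({
        "run": 1, "trial": np.arange(1, n + 1), "pair_id": pair,
        "condition": condition, "choice": list(choices),
        "outcome": 0.0, "go_flag": 0,
    })


def _random_table(rng, n=12):
    rows = []
    for i in range(n):
        for t in ("placebo", "vaccine"):
            for c in ("gain", "loss"):
                rows.append({"subject_id": f"s{i}", "treatment": t, "condition": c,
                             "y": rng.normal()})
    return pd.DataFrame(rows)


class TestLearningCurve:
    def test_all_correct_curve_is_one(self):
        curve = learning_curve(_cell(["A"] * 10), window=3)
        assert np.allclose(curve, 1.0)

    def test_window_one_returns_raw_sequence(self):
        cell = _cell(["A", "B", "A", "A"])
        assert np.allclose(learning_curve(cell, window=1), [1, 0, 1, 1])

    def test_simulated_learner_curve_rises_above_08(self):
        log = simulate_cell(alpha=0.5, beta=1e-3, r=1.0, seed=1, trials_per_pair=60)
        curve = learning_curve(log, window=5)
        assert curve[-1] > 0.8
        # averaged over many moderate learners the curve rises from chance
        curves = [
            learning_curve(
                simulate_cell(0.3, 0.25, 1.0, seed=s, trials_per_pair=30), window=5
            )
            for s in range(40)
        ]
        mean_curve = np.mean(curves, axis=0)
        assert mean_curve[:3].mean() < 0.7 < mean_curve[-5:].mean()

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            learning_curve(_cell(["A"] * 5), window=6)

    def test_neutral_condition_rejected(self):
        with pytest.raises(DesignError):
            learning_curve(_cell(["A"] * 5, condition="neutral"), window=1)


class TestPlateauAccuracy:
    def test_last_half_all_correct(self):
        acc = plateau_accuracy(_cell(["B"] * 5 + ["A"] * 5))
        assert acc == 1.0

    def test_always_approaching_loss_scores_zero(self):
        acc = plateau_accuracy(_cell(["A"] * 10, condition="loss"))
        assert acc == 0.0

    def test_random_agent_near_half(self):
        accs = [
            plateau_accuracy(simulate_cell(0.0, 0.3, 1.0, seed=s, trials_per_pair=40))
            for s in range(100)
        ]
        # pooled binomial error over 100 x 3 pairs x 20 plateau trials
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / (100 * 60))


class TestPairedT:
    def test_identical_vectors_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_offset_degenerate(self):
        with pytest.raises(DesignError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_matches_textbook_on_hand_example(self):
        x = [12.1, 10.3, 14.2, 9.8, 11.4]
        y = [11.0, 10.9, 12.5, 9.1, 10.8]
        res = paired_t(x, y)
        t_ref, p_ref = textbook_paired_t(x, y)
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)
        assert res.df == 4


class TestRmAnova:
    def test_zero_contrast_gives_zero_interaction(self):
        # purely additive (subject + treatment + condition) dyadic values:
        # the difference-of-differences is exactly zero for every subject
        rows = []
        for i in range(10):
            te, ce = 0.25 * i, -0.5 - 0.125 * i  # subject-varying, dyadic
            for t in ("placebo", "vaccine"):
                for c in ("gain", "loss"):
                    y = float(i) + te * (t == "vaccine") + ce * (c == "loss")
                    rows.append({"subject_id": f"s{i}", "treatment": t,
                                 "condition": c, "y": y})
        res = rm_anova_2x2(pd.DataFrame(rows), "y")
        assert res["interaction"].F == 0.0
        assert res["interaction"].p == 1.0
        assert res["treatment"].F > 0

    def test_interaction_f_is_squared_paired_t(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            table = _random_table(rng)
            wide = table.pivot_table(index="subject_id",
                                     columns=["treatment", "condition"], values="y")
            dod = (wide[("vaccine", "gain")] - wide[("placebo", "gain")]) - (
                wide[("vaccine", "loss")] - wide[("placebo", "loss")]
            )
            t_ref, p_ref = textbook_paired_t(list(dod), [0.0] * len(dod))
            res = rm_anova_2x2(table, "y")["interaction"]
            assert res.F == pytest.approx(t_ref**2, abs=1e-8)
            assert res.p == pytest.approx(p_ref, abs=1e-10)
            assert res.df == (1, len(dod) - 1)

    def test_agrees_with_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        table = _random_table(np.random.default_rng(3), n=16)
        ref = AnovaRM(table, "y", "subject_id",
                      within=["treatment", "condition"]).fit().anova_table
        res = rm_anova_2x2(table, "y")
        assert res["treatment"].F == pytest.approx(
            ref.loc["treatment", "F Value"], rel=1e-8)
        assert res["condition"].F == pytest.approx(
            ref.loc["condition", "F Value"], rel=1e-8)
        assert res["interaction"].F == pytest.approx(
            ref.loc["treatment:condition", "F Value"], rel=1e-8)

    def test_missing_cells_error_names_subjects(self):
        table = _random_table(np.random.default_rng(2))
        table = table[~((table.subject_id == "s3") & (table.treatment == "vaccine")
                        & (table.condition == "loss"))]
        with pytest.raises(DesignError, match="s3"):
            rm_anova_2x2(table, "y")

    def test_relabeling_treatments_preserves_f(self):
        table = _random_table(np.random.default_rng(4))
        res = rm_anova_2x2(table, "y")
        flipped = table.replace({"treatment": {"placebo": "vaccine", "vaccine": "placebo"}})
        res2 = rm_anova_2x2(flipped, "y")
        for eff in ("treatment", "condition", "interaction"):
            assert res2[eff].F == pytest.approx(res[eff].F, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_identity_fuzz(self, seed):
        table = _random_table(np.random.default_rng(seed), n=8)
        wide = table.pivot_table(index="subject_id", columns=["treatment", "condition"],
                                 values="y")
        dod = (wide[("vaccine", "gain")] - wide[("placebo", "gain")]) - (
            wide[("vaccine", "loss")] - wide[("placebo", "loss")]
        )
        t_ref, _ = textbook_paired_t(list(dod), [0.0] * len(dod))
        assert rm_anova_2x2(table, "y")["interaction"].F == pytest.approx(
            t_ref**2, abs=1e-8)


class TestCohortTable:
    def test_table_shape_and_ranges(self, tiny_study):
        from rlcross.fitting import FitSpec, fit_study

        fits, _ = fit_study(tiny_study.trials, FitSpec(seed=1))
        table = build_cohort_table(tiny_study.trials, fits)
        assert len(table) == 4 * 2 * 2
        assert table["plateau_accuracy"].between(0, 1).all()
        assert table["go_rate"].between(0, 1).all()
        assert (np.sign(table.loc[table.condition == "loss", "r"]) <= 0).all()
        assert (table["r_magnitude"] >= 0).all()

    def test_engagement_and_session_checks_run(self, tiny_study):
        from rlcross.fitting import FitSpec, fit_study

        fits, _ = fit_study(tiny_study.trials, FitSpec(seed=1))
        table = build_cohort_table(tiny_study.trials, fits)
        eng = engagement_check(table)
        assert set(eng) == {"treatment", "condition", "interaction"}
        sess = session_order_anova(table)
        assert sess["interaction"].df == (1, 3)

    def test_all_go_responder_has_unit_go_rate(self):
        cell = _cell(["A"] * 10)
        cell["go_flag"] = 1
        cell[["subject_id", "treatment"]] = ["s1", "placebo"]
        fits = pd.DataFrame([{"subject_id": "s1", "treatment": "placebo",
                              "condition": "gain", "alpha": .3, "beta": .3, "r": 1.0,
                              "mean_ll_per_pair": -5.0}])
        table = build_cohort_table(cell, fits)
        assert table["go_rate"].iloc[0] == 1.0

    def test_cell_paired_t_convention_vaccine_minus_placebo(self):
        rows = []
        for i, (p_val, v_val) in enumerate([(1.0, 2.0), (1.5, 2.1), (0.8, 1.9)]):
            rows.append({"subject_id": f"s{i}", "treatment": "placebo",
                         "condition": "gain", "y": p_val})
            rows.append({"subject_id": f"s{i}", "treatment": "vaccine",
                         "condition": "gain", "y": v_val})
        res = cell_paired_t(pd.DataFrame(rows), "y", "condition", "gain")
        assert res.mean_diff > 0  # vaccine larger
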