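"""Behavioral statistics: CP_log, distances, realized growth."""

import math

import numpy as np
import pytest
from scipy.stats import kendalltau

from ergochoice.agents import (
    AgentSpec,
    CohortSpec,
    calibrate_beta,
    default_study_cohort,
    sample_cohort,
    simulate_choices,
    simulate_study,
)
from ergochoice.metrics import (
    choice_proportion_log,
    distance_to_diagonal,
    distance_to_time_optimal,
    realized_growth_rate,
    subject_metrics,
)
from ergochoice.paradigm import (
    ActiveSession,
    Dynamic,
    Gamble,
    TrialPair,
    gamble_growth_rate,
    log_preferred_side,
)
from ergochoice.utility import UtilityModel, UtilityParams


class TestDistances:
    @pytest.mark.parametrize("ea,em,expected", [
        (0.0, 1.0, 0.0),
        (1.0, 1.0, 1.0),
        (0.1506, 1.1534, math.hypot(0.1506, 0.1534)),
    ])
    def test_distance_to_time_optimal(self, ea, em, expected):
        assert distance_to_time_optimal(ea, em) == pytest.approx(expected)

    def test_time_optimal_distance_zero_only_at_optimum(self):
        assert distance_to_time_optimal(0.0, 1.0) == 0.0
        for ea, em in ((0.01, 1.0), (0.0, 0.99), (1.0, 0.0)):
            assert distance_to_time_optimal(ea, em) > 0

    @pytest.mark.parametrize("ea,em,expected", [
        (0.7, 0.7, 0.0),
        (0.0, 1.0, 1 / math.sqrt(2)),
    ])
    def test_distance_to_diagonal(self, ea, em, expected):
        assert distance_to_diagonal(ea, em) == pytest.approx(expected)

    def test_diagonal_distance_symmetry(self):
        assert distance_to_diagonal(0.2, 0.9) == distance_to_diagonal(0.9, 0.2)


class TestChoiceProportionLog:
    def test_deterministic_log_agent_scores_one(self, sessions):
        sess = sessions[Dynamic.MULTIPLICATIVE]
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1e9))
        rows = simulate_choices(agent, sess, seed=1)
        assert choice_proportion_log(rows, sess).iloc[0] == 1.0

    def test_always_linear_choices_score_zero(self, sessions):
        sess = sessions[Dynamic.MULTIPLICATIVE]
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1e9))
        rows = simulate_choices(agent, sess, seed=1)
        # flip every discrepant-trial choice: CP_lin > 0.5 <=> CP_log < 0.5
        for i, t in enumerate(sess.trials):
            if t.is_discrepant:
                cur = rows.loc[rows.trial_index == i, "choice"].iloc[0]
                rows.loc[rows.trial_index == i, "choice"] = (
                    "right" if cur == "left" else "left")
        assert choice_proportion_log(rows, sess).iloc[0] == 0.0

    def test_random_agent_near_half(self, sessions):
        sess = sessions[Dynamic.MULTIPLICATIVE]
        big = ActiveSession(dynamic=sess.dynamic, trials=sess.trials * 30,
                            reference_wealth=sess.reference_wealth)
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1e-12))
        rows = simulate_choices(agent, big, seed=2)
        assert choice_proportion_log(rows, big).iloc[0] == pytest.approx(
            0.5, abs=0.06)

    def test_no_discrepant_trials_rejected(self, sessions):
        sess = sessions[Dynamic.MULTIPLICATIVE]
        only_nb = ActiveSession(
            dynamic=sess.dynamic,
            trials=tuple(t for t in sess.trials if t.is_nobrainer))
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1.0))
        rows = simulate_choices(agent, only_nb, seed=0)
        with pytest.raises(ValueError, match="discrepant"):
            choice_proportion_log(rows, only_nb)

    def test_time_cohort_cp_log_higher_under_multiplicative(self, sessions):
        """The headline direction: time-optimal cohorts favour log utility
        more under multiplicative than additive dynamics, at every seed."""
        for seed in range(4):
            cohort = sample_cohort(default_study_cohort(), seed=300 + seed)
            df = simulate_study(cohort, sessions, seed=400 + seed)
            cp_add = choice_proportion_log(df, sessions[Dynamic.ADDITIVE])
            cp_mult = choice_proportion_log(df, sessions[Dynamic.MULTIPLICATIVE])
            assert cp_mult.mean() > cp_add.mean()


class TestRealizedGrowth:
    def test_symmetric_mirror_session_is_growth_neutral(self):
        pair = TrialPair(left=Gamble((428.0, -107.0)),
                         right=Gamble((107.0, -428.0)))
        sess = ActiveSession(dynamic=Dynamic.ADDITIVE, trials=(pair,) * 40)
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1e-12))
        rows = simulate_choices(agent, sess, seed=3)
        g = realized_growth_rate(rows, sess)
        chosen = [gamble_growth_rate(
            Gamble((r.left_out1, r.left_out2)) if r.choice == "left"
            else Gamble((r.right_out1, r.right_out2)), Dynamic.ADDITIVE)
            for r in rows.itertuples()]
        assert g.iloc[0] == pytest.approx(np.mean(chosen))
        assert {abs(c) for c in chosen} == {160.5}  # +/- (428-107)/2

    def test_maximizing_agent_attains_session_maximum(self, sessions):
        sess = sessions[Dynamic.MULTIPLICATIVE]
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1e9))
        rows = simulate_choices(agent, sess, seed=4)
        oracle = np.mean([
            max(gamble_growth_rate(t.left, sess.dynamic),
                gamble_growth_rate(t.right, sess.dynamic))
            for t in sess.trials
        ])
        assert realized_growth_rate(rows, sess).iloc[0] == pytest.approx(oracle)

    def test_random_agent_matches_pair_average_oracle(self, sessions):
        sess = sessions[Dynamic.ADDITIVE]
        big = ActiveSession(dynamic=sess.dynamic, trials=sess.trials * 20)
        agent = AgentSpec("a", UtilityModel.TIME,
                          UtilityParams(model=UtilityModel.TIME, beta=1e-12))
        rows = simulate_choices(agent, big, seed=5)
        oracle = np.mean([
            0.5 * (gamble_growth_rate(t.left, sess.dynamic)
                   + gamble_growth_rate(t.right, sess.dynamic))
            for t in big.trials
        ])
        got = realized_growth_rate(rows, big).iloc[0]
        assert got == pytest.approx(oracle, abs=3.0)  # DKK/trial, MC error

    def test_growth_decreases_with_distance_from_optimum(self, sessions):
        """Across agents spanning eta in [-0.5, 1.5], the realized growth
        rate falls as risk aversion departs from the dynamic's optimum
        (negative rank correlation in at least 19 of 20 replicates)."""
        for dynamic in Dynamic:
            sess = sessions[dynamic]
            opt = dynamic.optimal_eta
            etas = np.linspace(-0.5, 1.5, 12)
            hits = 0
            for rep in range(20):
                growths = []
                for i, eta in enumerate(etas):
                    beta = calibrate_beta(dynamic, eta=opt)
                    agent = AgentSpec(
                        f"a{i}", UtilityModel.ISO,
                        UtilityParams(model=UtilityModel.ISO, eta=float(eta),
                                      beta=beta))
                    rows = simulate_choices(agent, sess, seed=1000 * rep + i)
                    growths.append(realized_growth_rate(rows, sess).iloc[0])
                tau, _ = kendalltau(np.abs(etas - opt), growths)
                hits += tau < 0
            assert hits >= 19, f"{dynamic.value}: only {hits}/20 negative"


class TestSubjectMetricsTable:
    def test_tidy_table_contents(self, sessions, study_data):
        eta_map = {sid: {Dynamic.ADDITIVE: 0.1, Dynamic.MULTIPLICATIVE: 0.9}
                   for sid in study_data["subject_id"].unique()}
        tbl = subject_metrics(study_data, sessions, eta_map)
        assert len(tbl) == 18
        assert {"cp_log_additive", "cp_log_multiplicative", "delta_cp_log",
                "growth_additive", "growth_multiplicative",
                "dist_time_optimal", "dist_diagonal"} <= set(tbl.columns)
        assert ((tbl["cp_log_additive"] >= 0) & (tbl["cp_log_additive"] <= 1)).all()
        assert (tbl["dist_time_optimal"] >= 0).all()
        assert np.allclose(tbl["delta_cp_log"],
                           tbl["cp_log_multiplicative"] - tbl["cp_log_additive"])
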