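"""Paradigm construction: stimulus sets, passive sequences, gamble space."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergochoice.paradigm import (
    ActiveSession,
    Dynamic,
    Gamble,
    TrialPair,
    WealthTrajectory,
    apply_outcome,
    build_active_session,
    build_gamble_space,
    classify_discrepant,
    finite_time_growth,
    gamble_growth_rate,
    generate_passive_sequence,
    make_stimulus_set,
)


class TestStimulusSets:
    def test_canonical_additive_values(self):
        ss = make_stimulus_set(Dynamic.ADDITIVE, 428)
        assert ss.values == (-428, -321, -214, -107, 0, 107, 214, 321, 428)
        assert len(ss.gains) == 4 and len(ss.losses) == 4

    def test_canonical_multiplicative_values(self):
        ss = make_stimulus_set(Dynamic.MULTIPLICATIVE, 2.0)
        np.testing.assert_allclose(ss.values, 2.0 ** (np.arange(-4, 5) / 4))
        assert len(ss.gains) == 4 and len(ss.losses) == 4

    @pytest.mark.parametrize("dynamic,extreme", [
        (Dynamic.ADDITIVE, 0.0), (Dynamic.ADDITIVE, -1.0),
        (Dynamic.MULTIPLICATIVE, 1.0), (Dynamic.MULTIPLICATIVE, 0.5),
    ])
    def test_degenerate_extreme_rejected(self, dynamic, extreme):
        with pytest.raises(ValueError):
            make_stimulus_set(dynamic, extreme)

    @pytest.mark.parametrize("dynamic", list(Dynamic))
    def test_conservation(self, dynamic, stimulus_sets):
        """Increments sum to zero; log-factors sum to zero."""
        v = np.asarray(stimulus_sets[dynamic].values)
        if dynamic is Dynamic.ADDITIVE:
            assert v.sum() == 0
        else:
            assert abs(np.log(v).sum()) < 1e-12


class TestWealthUpdates:
    @pytest.mark.parametrize("wealth,outcome,dynamic,expected", [
        (1000, 428, Dynamic.ADDITIVE, 1428),
        (1000, 2.0, Dynamic.MULTIPLICATIVE, 2000),
        (1000, 0, Dynamic.ADDITIVE, 1000),
    ])
    def test_apply_outcome(self, wealth, outcome, dynamic, expected):
        assert apply_outcome(wealth, outcome, dynamic) == expected

    def test_multiplicative_requires_positive_wealth(self):
        with pytest.raises(ValueError):
            apply_outcome(-5.0, 2.0, Dynamic.MULTIPLICATIVE)


class TestPassiveSequence:
    @pytest.mark.parametrize("dynamic", list(Dynamic))
    def test_balanced_block_returns_to_endowment(self, dynamic, stimulus_sets):
        traj = generate_passive_sequence(stimulus_sets[dynamic], seed=7)
        assert traj.n_trials == 334  # 333 balanced + 1 extra
        # each stimulus appears exactly 37 times in the balanced block
        vals, counts = np.unique(traj.outcomes[:333], return_counts=True)
        assert len(vals) == 9 and set(counts) == {37}
        assert traj.wealth[333] == pytest.approx(1000.0, rel=1e-9)
        assert np.all(traj.wealth > 0) and np.all(traj.wealth < 5000)

    def test_deterministic_given_seed(self, stimulus_sets):
        a = generate_passive_sequence(stimulus_sets[Dynamic.ADDITIVE], seed=3)
        b = generate_passive_sequence(stimulus_sets[Dynamic.ADDITIVE], seed=3)
        np.testing.assert_array_equal(a.outcomes, b.outcomes)

    def test_unreachable_bounds_raise_with_attempt_count(self, stimulus_sets):
        with pytest.raises(RuntimeError, match="rejection attempts"):
            generate_passive_sequence(stimulus_sets[Dynamic.ADDITIVE],
                                      bounds=(999.0, 1001.0),
                                      seed=0, max_attempts=50)

    def test_invalid_initial_wealth(self, stimulus_sets):
        with pytest.raises(ValueError):
            generate_passive_sequence(stimulus_sets[Dynamic.ADDITIVE],
                                      bounds=(0, 500), initial_wealth=1000,
                                      seed=0)


class TestGrowthRates:
    def test_balanced_block_growth_is_zero(self, stimulus_sets):
        for dynamic in Dynamic:
            traj = generate_passive_sequence(stimulus_sets[dynamic], seed=5)
            balanced = WealthTrajectory(
                dynamic=dynamic, initial_wealth=1000.0,
                outcomes=traj.outcomes[:333], wealth=traj.wealth[:334])
            assert finite_time_growth(balanced) == pytest.approx(0.0, abs=1e-12)

    def test_single_trial_coin_gamble_growth(self):
        w1 = apply_outcome(1000.0, math.sqrt(1.5 * 0.6), Dynamic.MULTIPLICATIVE)
        traj = WealthTrajectory(dynamic=Dynamic.MULTIPLICATIVE,
                                initial_wealth=1000.0,
                                outcomes=np.array([math.sqrt(1.5 * 0.6)]),
                                wealth=np.array([1000.0, w1]))
        assert finite_time_growth(traj) == pytest.approx(math.log(math.sqrt(0.9)))

    def test_empty_trajectory_rejected(self):
        traj = WealthTrajectory(dynamic=Dynamic.ADDITIVE, initial_wealth=1000.0,
                                outcomes=np.array([]), wealth=np.array([1000.0]))
        with pytest.raises(ValueError):
            finite_time_growth(traj)

    def test_gamble_growth_examples(self):
        assert gamble_growth_rate(Gamble((428.0, -428.0)), Dynamic.ADDITIVE) == 0
        g = Gamble((1.5, 0.6))
        assert gamble_growth_rate(g, Dynamic.MULTIPLICATIVE) == pytest.approx(
            math.log(math.sqrt(0.9)))
        # the expectation-value counterpart of the same gamble
        assert np.mean(g.outcomes) == pytest.approx(1.05)

    @given(a=st.floats(0.2, 3.0), b=st.floats(0.2, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_growth_agrees_with_single_trial_enumeration(self, a, b):
        """Oracle: the gamble growth rate equals the mean single-trial
        finite-time growth over the two equiprobable outcomes."""
        g = Gamble((a, b))
        enumerated = np.mean([
            math.log(apply_outcome(1000.0, s, Dynamic.MULTIPLICATIVE) / 1000.0)
            for s in g.outcomes
        ])
        assert gamble_growth_rate(g, Dynamic.MULTIPLICATIVE) == pytest.approx(
            enumerated, rel=1e-12)


class TestGambleSpace:
    @pytest.mark.parametrize("dynamic", list(Dynamic))
    def test_constrained_space_counts(self, dynamic, stimulus_sets):
        mixed, pairs = build_gamble_space(stimulus_sets[dynamic])
        assert len(mixed) == len(stimulus_sets[dynamic].gains) * \
            len(stimulus_sets[dynamic].losses) == 16
        assert len(pairs) == 144
        for p in pairs:
            assert len(set(p.outcome_values)) == 4

    def test_pair_count_formula(self, stimulus_sets):
        """|pairs| = |mixed| * (gains-1)(losses-1)."""
        ss = stimulus_sets[Dynamic.ADDITIVE]
        mixed, pairs = build_gamble_space(ss)
        ng, nl = len(ss.gains), len(ss.losses)
        assert len(pairs) == len(mixed) * (ng - 1) * (nl - 1)


class TestDiscrepancy:
    def test_identical_gambles_not_discrepant(self):
        g = Gamble((2.0, 0.5))
        pair = TrialPair(left=g, right=g)
        assert not classify_discrepant(pair, Dynamic.MULTIPLICATIVE, 1000.0)

    def test_canonical_multiplicative_discrepant_pair(self):
        # linear means 1.25 vs ~1.128 prefer left; log means 0 vs +0.087 prefer right
        pair = TrialPair(left=Gamble((2.0, 0.5)),
                         right=Gamble((2 ** 0.5, 2 ** -0.25)))
        assert classify_discrepant(pair, Dynamic.MULTIPLICATIVE, 1000.0)

    def test_additive_pair_with_agreeing_criteria(self):
        pair = TrialPair(left=Gamble((428.0, -107.0)),
                         right=Gamble((107.0, -428.0)))
        assert not classify_discrepant(pair, Dynamic.ADDITIVE, 1000.0)

    def test_structural_log_tie_is_not_discrepant(self):
        # both gambles have mean log factor exactly zero
        pair = TrialPair(left=Gamble((2.0, 0.5)),
                         right=Gamble((2 ** 0.5, 2 ** -0.5)))
        assert not classify_discrepant(pair, Dynamic.MULTIPLICATIVE, 1000.0)

    def test_nonpositive_reference_wealth_rejected(self):
        pair = TrialPair(left=Gamble((2.0, 0.5)), right=Gamble((1.5, 0.7)))
        with pytest.raises(ValueError):
            classify_discrepant(pair, Dynamic.MULTIPLICATIVE, 0.0)

    @given(w=st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative_discrepancy_is_wealth_invariant(self, w):
        _, pairs = build_gamble_space(make_stimulus_set(Dynamic.MULTIPLICATIVE))
        ref = [classify_discrepant(p, Dynamic.MULTIPLICATIVE, 1000.0)
               for p in pairs[::7]]
        got = [classify_discrepant(p, Dynamic.MULTIPLICATIVE, w)
               for p in pairs[::7]]
        assert got == ref


class TestActiveSession:
    def test_session_composition(self, sessions):
        for dynamic, sess in sessions.items():
            assert sess.n_trials == 312
            mixed = [t for t in sess.trials if not t.is_nobrainer]
            assert len(mixed) == 288
            # each of the 144 constrained ordered pairs appears exactly twice
            keys = [t.outcome_values for t in mixed]
            _, counts = np.unique(keys, axis=0, return_counts=True)
            assert len(counts) == 144 and set(counts) == {2}

    def test_nobrainers_are_statewise_dominated(self, sessions):
        for sess in sessions.values():
            nb = [t for t in sess.trials if t.is_nobrainer]
            assert len(nb) == 24
            for t in nb:
                shared = set(t.left.outcomes) & set(t.right.outcomes)
                assert len(shared) == 1
                l = sorted(t.left.outcomes)
                r = sorted(t.right.outcomes)
                assert (all(a >= b for a, b in zip(l, r)) and l != r) or \
                       (all(a <= b for a, b in zip(l, r)) and l != r)

    def test_reproducible_from_seed(self, stimulus_sets):
        s1 = build_active_session(stimulus_sets[Dynamic.ADDITIVE], seed=9)
        s2 = build_active_session(stimulus_sets[Dynamic.ADDITIVE], seed=9)
        assert [t.outcome_values for t in s1.trials] == \
               [t.outcome_values for t in s2.trials]

    def test_too_many_nobrainers_rejected(self, stimulus_sets):
        with pytest.raises(ValueError):
            build_active_session(stimulus_sets[Dynamic.ADDITIVE],
                                 n_nobrainers=1000, seed=0)

    def test_unordered_mode_keeps_trial_count(self, stimulus_sets):
        sess = build_active_session(stimulus_sets[Dynamic.ADDITIVE], seed=4,
                                    unordered_pairs=True)
        assert sess.n_trials == 312
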