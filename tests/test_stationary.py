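"""Stationary two-armed bandit: information states, exact solution, bonuses."""

from fractions import Fraction

import pytest

from choicemdp.core import SpecError, backward_induction
from choicemdp.stationary import (
    BanditJointState,
    BetaArmState,
    _LayeredValues,
    arm_transition,
    bandit_spec,
    exploration_bonus,
    heuristic_two_phase_value,
    parse_sequence,
    posterior_mean,
    scenario_eval,
    solve_bandit,
)
from oracles import expectimax_utility


def joint(a1, a2):
    return BanditJointState(a1, a2)


ROOT = joint(BetaArmState(0, 0), BetaArmState(0, 0))


class TestArmState:
    @pytest.mark.parametrize(
        "arm,expected",
        [
            (BetaArmState(0, 0), 0.5),           # unsampled, vague prior
            (BetaArmState(3, 6), 0.5),           # 3 of 6 rewarded
            (BetaArmState(5, 5), 6 / 7),         # all rewarded
            (BetaArmState(0, 0, 2.0, 2.0), 0.5),
        ],
    )
    def test_posterior_mean(self, arm, expected):
        assert posterior_mean(arm) == pytest.approx(expected)

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(SpecError, match="positive"):
            BetaArmState(0, 0, 0.0, 1.0)

    def test_reward_count_cannot_exceed_choices(self):
        with pytest.raises(SpecError):
            BetaArmState(3, 2)

    def test_root_transition_is_even_split(self):
        (up, p_up), (dn, p_dn) = arm_transition(BetaArmState(0, 0))
        assert p_up == pytest.approx(0.5) and p_dn == pytest.approx(0.5)
        assert (up.r, up.c) == (1, 1) and (dn.r, dn.c) == (0, 1)

    def test_transition_probabilities_sum_to_one(self):
        for r, c in [(0, 0), (2, 5), (7, 7)]:
            assert sum(p for _, p in arm_transition(BetaArmState(r, c))) == pytest.approx(1.0)

    def test_posterior_mean_is_martingale_exact(self):
        """(R/C)(R+1)/(C+1) + (1-R/C) R/(C+1) = R/C, in exact arithmetic."""
        for r in range(8):
            for c in range(r, 8):
                R, C = Fraction(r + 1), Fraction(c + 2)
                lhs = (R / C) * (R + 1) / (C + 1) + (1 - R / C) * R / (C + 1)
                assert lhs == R / C


class TestSolver:
    def test_one_trial_horizon_is_myopic(self):
        start = joint(BetaArmState(4, 5), BetaArmState(1, 5))
        sol = solve_bandit(start=start, horizon=1)
        assert sol.chosen(1, start) == 1
        assert sol.utility(1, start) == pytest.approx(posterior_mean(start.arm1))

    def test_symmetric_state_has_equal_action_values(self):
        sol = solve_bandit(horizon=6)
        s = ROOT
        assert sol.action_value(1, s, 1) == pytest.approx(sol.action_value(1, s, 2))

    @pytest.mark.parametrize("horizon", [2, 3, 5])
    def test_matches_exhaustive_tree_enumeration(self, horizon):
        start = joint(BetaArmState(1, 2), BetaArmState(0, 1))
        spec = bandit_spec(start, horizon)
        sol = backward_induction(spec)
        assert sol.utility(1, start) == pytest.approx(expectimax_utility(spec, start, 1), abs=1e-10)

    def test_layered_solver_equals_generic_solver(self):
        sol = solve_bandit(horizon=6)
        lv = _LayeredValues(ROOT, 6)
        assert lv.u[0][0] == pytest.approx(sol.utility(1, ROOT), abs=1e-12)
        vals = lv.at_state(0, 0, 0, 0)
        assert vals["Q1"] == pytest.approx(sol.action_value(1, ROOT, 1), abs=1e-12)

    def test_oversized_horizon_raises_resource_error(self):
        with pytest.raises(SpecError, match="information states"):
            solve_bandit(horizon=500)


class TestExplorationBonus:
    def test_zero_future_means_zero_bonus(self):
        s = joint(BetaArmState(3, 6), BetaArmState(0, 0))
        assert exploration_bonus(s, 1) == pytest.approx(0.0)

    def test_unsampled_arm_favored_despite_equal_iev(self):
        s = joint(BetaArmState(3, 6), BetaArmState(0, 0))
        assert exploration_bonus(s, 50) > 0
        lv = _LayeredValues(s, 50)
        vals = lv.at_state(0, 0, 0, 0)
        assert vals["iev1"] == pytest.approx(vals["iev2"])   # both 0.5
        assert vals["Q2"] > vals["Q1"]

    def test_bonus_nondecreasing_in_horizon_at_thrice_rewarded_state(self):
        s = joint(BetaArmState(3, 3), BetaArmState(0, 0))
        bonuses = [exploration_bonus(s, n) for n in (5, 10, 20, 50)]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bonuses, bonuses[1:]))
        assert bonuses[-1] > bonuses[0]

    def test_identical_arms_have_zero_bonus(self):
        s = joint(BetaArmState(2, 4), BetaArmState(2, 4))
        assert exploration_bonus(s, 20) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_prior_kills_the_bonus(self):
        """Two arms with the same near-certain mean: nothing to learn,
        no exploration bonus (sharp-prior limit)."""
        sharp = BetaArmState(0, 0, 500.0, 500.0)
        sampled = BetaArmState(3, 6, 500.0, 500.0)
        bonus = exploration_bonus(joint(sampled, sharp), 30)
        assert abs(bonus) < 1e-3


class TestScenarioEval:
    def test_empty_sequence_reports_prior_values(self):
        recs = scenario_eval("", 8)
        assert len(recs) == 1
        assert recs[0]["iev1"] == pytest.approx(0.5) and recs[0]["iev2"] == pytest.approx(0.5)

    def test_reward_streak_then_miss_flips_preference(self):
        recs = scenario_eval("1+ 1+ 1+ 1-", 50)
        # during the streak option 1 leads on total value but trails on FEV
        for t in (1, 2, 3):
            assert recs[t]["fev2"] > recs[t]["fev1"]
        assert recs[4]["Q2"] > recs[4]["Q1"]

    def test_matched_histories_equalize_action_values(self):
        recs = scenario_eval("1+ 1+ 1+ 1- 1- 1- 2+ 2+ 2+ 2- 2- 2-", 50)
        assert recs[6]["Q2"] > recs[6]["Q1"]      # trial 7: 3/6 vs unsampled
        assert recs[12]["Q1"] == pytest.approx(recs[12]["Q2"], abs=1e-12)

    def test_malformed_token_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            parse_sequence("1+ 3x 2-")


class TestTwoPhaseHeuristic:
    def test_worked_example(self):
        out = heuristic_two_phase_value(0.7, 0.8, 0.2, 10, 100)
        assert out["stay_value"] == pytest.approx(70.0)
        assert out["branch_hi"] == pytest.approx(80.0)
        assert out["branch_lo"] == pytest.approx(65.0)
        assert out["average"] == pytest.approx(72.5)
        assert out["bonus"] == pytest.approx(2.5)

    def test_probability_range_checked(self):
        with pytest.raises(SpecError):
            heuristic_two_phase_value(1.2, 0.8, 0.2, 10, 100)
        with pytest.raises(SpecError):
            heuristic_two_phase_value(0.7, 0.8, 0.2, 0, 100)
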