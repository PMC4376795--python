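"""Exact-solver unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choicemdp.core import (
    ConvergenceError,
    SpecError,
    TaskSpec,
    backward_induction,
    greedy_policy,
    q_decompose,
    value_iteration,
)
from oracles import expectimax_utility, random_taskspec


def _chain(reward=1.0, gamma=1.0, horizon=3):
    return TaskSpec(
        actions=lambda s: (0,),
        reward=lambda s, a: reward,
        transitions=lambda s, a: [("s", 1.0)],
        discount=gamma,
        horizon=horizon,
        start=["s"],
        states=["s"],
    )


class TestBackwardInduction:
    def test_reward_chain_sums_rewards(self):
        sol = backward_induction(_chain(horizon=3))
        assert sol.utility(1, "s") == pytest.approx(3.0)

    def test_transient_reward_gap_persists_in_finite_horizon(self, fig8_spec):
        from dataclasses import replace

        for gamma in (0.3, 0.9, 0.99):
            spec = replace(fig8_spec, discount=gamma, horizon=60)
            sol = backward_induction(spec)
            gap = sol.action_value(1, "s1", 1) - sol.action_value(1, "s1", 2)
            assert gap == pytest.approx(999.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        spec = random_taskspec(seed, n_states=2, n_actions=2, horizon=4)
        sol = backward_induction(spec)
        for s in spec.states:
            assert sol.utility(1, s) == pytest.approx(expectimax_utility(spec, s, 1), abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True, database=None)
    def test_enumeration_property_sweep(self, seed):
        """Solver equals brute force on small random specs (<=3 states, N<=5)."""
        rng = np.random.default_rng(seed)
        spec = random_taskspec(seed, n_states=int(rng.integers(1, 4)), n_actions=int(rng.integers(1, 3)),
                               horizon=int(rng.integers(1, 6)))
        sol = backward_induction(spec)
        assert sol.utility(1, 0) == pytest.approx(expectimax_utility(spec, 0, 1), abs=1e-9)

    def test_utilities_invariant_under_state_relabeling(self):
        spec = random_taskspec(7, n_states=3, n_actions=2, horizon=4)
        relabel = {0: "zebra", 1: "ant", 2: "moth"}
        renamed = TaskSpec(
            actions=lambda s: spec.actions(0),
            reward=lambda s, a: spec.reward({v: k for k, v in relabel.items()}[s], a),
            transitions=lambda s, a: [
                (relabel[j], p) for j, p in spec.transitions({v: k for k, v in relabel.items()}[s], a)
            ],
            discount=spec.discount,
            horizon=spec.horizon,
            start=[relabel[0]],
        )
        a, b = backward_induction(spec), backward_induction(renamed)
        for s in range(3):
            assert a.u.get((2, s)) is None or a.u[(2, s)] == pytest.approx(b.u[(2, relabel[s])])
        assert a.utility(1, 0) == pytest.approx(b.utility(1, "zebra"))

    def test_non_normalized_transitions_rejected(self):
        spec = TaskSpec(
            actions=lambda s: (0,),
            reward=lambda s, a: 1.0,
            transitions=lambda s, a: [("s", 0.7)],
            horizon=2,
            start=["s"],
        )
        with pytest.raises(SpecError, match="sum to"):
            backward_induction(spec)

    def test_unreachable_state_lookup_names_state(self):
        sol = backward_induction(_chain())
        with pytest.raises(LookupError, match="ghost"):
            sol.utility(1, "ghost")


class TestValueIteration:
    def test_geometric_series_fixed_point(self):
        spec = _chain(reward=2.0, gamma=0.5, horizon="infinite")
        sol = value_iteration(spec, tol=1e-10)
        assert sol.utility(0, "s") == pytest.approx(4.0, abs=1e-6)

    def test_average_reward_ignores_transient(self, fig8_spec):
        """Undiscounted, both actions at state 1 yield gain 1: the
        one-off 1000 is a transient and does not change the average."""
        sol = value_iteration(fig8_spec, criterion="span", tol=1e-10)
        assert sol.meta["gain"] == pytest.approx(1.0, abs=1e-6)
        # the differential values still record the transient preference
        assert sol.action_value(0, "s1", 1) - sol.action_value(0, "s1", 2) == pytest.approx(999.0, abs=1e-6)

    def test_discounted_favors_transient(self, fig8_spec):
        from dataclasses import replace

        sol = value_iteration(replace(fig8_spec, discount=0.9), tol=1e-10)
        assert sol.chosen(0, "s1") == 1

    def test_agrees_with_long_horizon_backward_induction(self):
        spec = random_taskspec(3, n_states=3, n_actions=2, horizon=500)
        spec.discount = 0.9
        vi = value_iteration(spec, tol=1e-10)
        bi = backward_induction(spec)
        for s in spec.states:
            assert vi.utility(0, s) == pytest.approx(bi.utility(1, s), abs=1e-6)

    def test_gamma_one_requires_span(self):
        with pytest.raises(SpecError, match="span"):
            value_iteration(_chain(horizon="infinite"), criterion="max-norm")

    def test_nonconvergence_reports_last_measure(self):
        spec = _chain(reward=1.0, gamma=0.999, horizon="infinite")
        with pytest.raises(ConvergenceError, match="max-norm"):
            value_iteration(spec, tol=1e-14, max_iter=5)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_contraction_bound_on_iterates(self, seed):
        """||v_{n+1} - v*|| <= gamma ||v_n - v*|| for gamma < 1."""
        spec = random_taskspec(seed, n_states=3, n_actions=2)
        spec.discount = 0.9
        spec.horizon = "infinite"
        sol = value_iteration(spec, tol=1e-13, record_history=True)
        vstar = np.array([sol.utility(0, s) for s in spec.states])
        hist = sol.meta["history"]
        for v_n, v_n1 in zip(hist[:-1], hist[1:]):
            lhs = np.max(np.abs(v_n1 - vstar))
            rhs = spec.discount * np.max(np.abs(v_n - vstar)) + 1e-12
            assert lhs <= rhs


class TestDecompositionAndPolicy:
    def test_terminal_trial_has_zero_fev(self):
        spec = _chain()
        out = q_decompose(spec, None, 3, "s")
        assert out[0][1] == 0.0 and out[0][2] == out[0][0]

    def test_zero_reward_everywhere_q_equals_fev(self):
        spec = TaskSpec(
            actions=lambda s: (0, 1),
            reward=lambda s, a: 0.0,
            transitions=lambda s, a: [("a", 0.5), ("b", 0.5)],
            discount=0.9,
            horizon=3,
            start=["a"],
        )
        out = q_decompose(spec, {"a": 2.0, "b": 4.0}, 1, "a")
        for iev, fev, q in out.values():
            assert iev == 0.0 and q == fev == pytest.approx(0.9 * 3.0)

    def test_decomposition_matches_independent_summation(self):
        spec = random_taskspec(21)
        rng = np.random.default_rng(0)
        u_next = {s: float(rng.normal()) for s in spec.states}
        out = q_decompose(spec, u_next, 1, 0)
        for a, (iev, fev, q) in out.items():
            direct = spec.reward(0, a) + spec.cost(0, a) + spec.discount * sum(
                p * u_next[j] for j, p in spec.transitions(0, a)
            )
            assert q == pytest.approx(direct, abs=1e-12)
            assert q == iev + fev

    def test_missing_successor_utility_is_lookup_error(self):
        spec = random_taskspec(2)
        with pytest.raises(LookupError, match="missing successor"):
            q_decompose(spec, {}, 1, 0)

    def test_tie_breaks_to_lowest_index(self):
        q = {(1, "s", a): 0.5 for a in ("x", "y", "z")}
        assert greedy_policy(q)[(1, "s")] == "x"

    def test_strict_maximizer_chosen(self):
        q = {(1, "s", "x"): 0.1, (1, "s", "y"): 0.9}
        assert greedy_policy(q)[(1, "s")] == "y"

    def test_seeded_random_ties_reproducible(self):
        q = {(1, "s", a): 1.0 for a in range(5)}
        picks = [greedy_policy(q, tie_rule="random", seed=42)[(1, "s")] for _ in range(3)]
        assert len(set(picks)) == 1
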