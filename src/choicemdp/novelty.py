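"""3-armed Beta-Bernoulli bandit with stochastic novel-option substitution.

Identical in spirit to the stationary bandit — each arm's information
state is its posterior count pair (R, C) under a Beta(1, 1) prior — but
on every trial, with probability ``p_switch``, one of the three arms
(uniformly chosen, possibly the arm just sampled) is replaced by a novel
option, which resets it to the prior root (R, C) = (1, 2).  Substitution
keeps the problem recurrent, so the task is modeled as an infinite-
horizon discounted POMDP and solved approximately on a per-arm
(N = C, p = R/C) coordinate grid with a B-spline basis.  A freshly
reset arm has maximal uncertainty and hence an elevated FEV — the
novelty bonus — which grows with the discount (longer effective
horizon) and shrinks with the substitution rate (less time to exploit
what is learned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ApproxValueFunction, BasisSpec, DimensionBasis, approximate_value_iteration
from .core import SpecError, TaskSpec

__all__ = [
    "NoveltyState",
    "RESET_ARM",
    "novelty_successors",
    "all_successors",
    "default_novelty_basis",
    "solve_novelty",
    "NoveltyModel",
    "novelty_bonus",
    "horizon_from_discount",
]

#: a substituted arm restarts at the Beta(1, 1) root: R = 1, C = 2
RESET_ARM = (2.0, 0.5)  # (N, p) coordinates


@dataclass(frozen=True)
class NoveltyState:
    """Per-arm (N, p) = (posterior choices C, posterior mean R/C) triple."""

    arms: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    p_switch: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.p_switch <= 1.0):
            raise SpecError(f"p_switch must lie in [0, 1], got {self.p_switch}")
        for n, p in self.arms:
            if n <= 0 or not (0.0 <= p <= 1.0):
                raise SpecError(f"invalid arm coordinates (N={n}, p={p})")

    @classmethod
    def from_counts(cls, counts: list[tuple[int, int]], p_switch: float = 0.05) -> "NoveltyState":
        """Build from raw (r, c) observation counts under a Beta(1,1) prior."""
        arms = tuple((c + 2.0, (r + 1.0) / (c + 2.0)) for r, c in counts)
        return cls(arms, p_switch)

    def coords(self) -> tuple[float, ...]:
        return tuple(x for arm in self.arms for x in arm)


def novelty_successors(state: NoveltyState, arm: int) -> list[tuple[NoveltyState, float]]:
    """Successor distribution for sampling ``arm`` (1-based).

    Seven distinct branches: {reward, no reward} with no substitution,
    {reward, no reward} x substitution of each *other* arm, and a single
    merged branch for substitution of the chosen arm itself (the reset
    wipes the outcome, so rewarded and unrewarded land in the same
    state).  Probabilities use q = p_i and the uniform-over-arms
    substitution factor p_switch/3; they sum to 1 exactly.
    """
    if arm not in (1, 2, 3):
        raise SpecError(f"arm must be 1, 2 or 3, got {arm}")
    i = arm - 1
    n, p = state.arms[i]
    ps = state.p_switch
    q = p

    def with_arm(arms, j, new):
        arms = list(arms)
        arms[j] = new
        return tuple(arms)

    rewarded = (n + 1.0, (p * n + 1.0) / (n + 1.0))
    unrewarded = (n + 1.0, (p * n) / (n + 1.0))
    out: list[tuple[NoveltyState, float]] = []
    # no substitution
    out.append((NoveltyState(with_arm(state.arms, i, rewarded), ps), q * (1.0 - ps)))
    out.append((NoveltyState(with_arm(state.arms, i, unrewarded), ps), (1.0 - q) * (1.0 - ps)))
    # substitution of one of the other two arms
    for j in range(3):
        if j == i:
            continue
        base_r = with_arm(with_arm(state.arms, i, rewarded), j, RESET_ARM)
        base_u = with_arm(with_arm(state.arms, i, unrewarded), j, RESET_ARM)
        out.append((NoveltyState(base_r, ps), q * ps / 3.0))
        out.append((NoveltyState(base_u, ps), (1.0 - q) * ps / 3.0))
    # substitution of the chosen arm: outcome is wiped, branches merge
    out.append((NoveltyState(with_arm(state.arms, i, RESET_ARM), ps), ps / 3.0))
    total = sum(pr for _, pr in out)
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"novelty successor probabilities sum to {total}")
    return out


def all_successors(state: NoveltyState) -> set[NoveltyState]:
    """Union of successors over the three actions (21 states generically)."""
    out: set[NoveltyState] = set()
    for arm in (1, 2, 3):
        out.update(s for s, _ in novelty_successors(state, arm))
    return out


def default_novelty_basis(
    n_knots: tuple[float, ...] = (0.0, 150.0),
    p_knots: tuple[float, ...] = (0.0, 1.0),
    n_grid: tuple[float, ...] | None = None,
    p_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> BasisSpec:
    """Cubic B-spline basis over per-arm (N, p), pairwise interactions.

    The N evaluation points default to exp(0 : 5/4 : 5), a geometric
    ladder from 1 to ~148 spanning the 0-150 knot range; N values need
    not be integers for evaluating the fitted function.
    """
    if n_grid is None:
        n_grid = tuple(np.exp(np.arange(0.0, 5.0 + 1e-9, 1.25)))
    n_dim = DimensionBasis("bspline", order=3, knots=n_knots)
    p_dim = DimensionBasis("bspline", order=3, knots=p_knots)
    return BasisSpec(
        dimensions=[n_dim, p_dim, n_dim, p_dim, n_dim, p_dim],
        interaction_order=2,
        evaluation_grid=[n_grid, p_grid, n_grid, p_grid, n_grid, p_grid],
    )


@dataclass
class NoveltyModel:
    """Fitted novelty-task value function and its one-step analytics."""

    value: ApproxValueFunction
    gamma: float
    p_switch: float

    def action_values(self, state: NoveltyState) -> dict[int, tuple[float, float, float]]:
        """Per-arm (IEV, FEV, Q) via one Bellman backup through v_hat."""
        out = {}
        for arm in (1, 2, 3):
            succ = novelty_successors(state, arm)
            coords = np.array([s.coords() for s, _ in succ])
            probs = np.array([p for _, p in succ])
            iev = state.arms[arm - 1][1]
            fev = self.gamma * float(probs @ self.value(coords))
            out[arm] = (iev, fev, iev + fev)
        return out


def solve_novelty(
    gamma: float = 0.95,
    p_switch: float = 0.05,
    basis: BasisSpec | None = None,
    tol: float = 1e-3,
    max_iter: int = 100_000,
) -> NoveltyModel:
    """Fit the 6-D novelty value function by approximate value iteration."""
    if basis is None:
        basis = default_novelty_basis()

    def actions(s):
        return (1, 2, 3)

    def reward(s, a):
        return s[2 * (a - 1) + 1]  # p coordinate of the chosen arm

    def transitions(s, a):
        st = NoveltyState(((s[0], s[1]), (s[2], s[3]), (s[4], s[5])), p_switch)
        return [(succ.coords(), pr) for succ, pr in novelty_successors(st, a)]

    grid = [tuple(row) for row in basis.grid_points()]
    spec = TaskSpec(
        actions=actions,
        reward=reward,
        transitions=transitions,
        discount=gamma,
        states=grid,
        name="novelty-bandit",
    )
    vf = approximate_value_iteration(spec, basis, tol=tol, max_iter=max_iter)
    return NoveltyModel(value=vf, gamma=gamma, p_switch=p_switch)


def novelty_bonus(
    state: NoveltyState,
    model: NoveltyModel,
    reset_arm: int = 1,
    comparison_arm: int = 2,
) -> float:
    """Q(reset arm) - Q(comparison arm) at ``state`` under the fitted model."""
    q = model.action_values(state)
    return q[reset_arm][2] - q[comparison_arm][2]


def horizon_from_discount(gamma: float) -> float:
    """Trial count at which exponential discounting reaches 1/e: -1/ln(gamma)."""
    if not (0.0 < gamma < 1.0):
        raise SpecError(f"gamma must lie in (0, 1), got {gamma}")
    return -1.0 / np.log(gamma)
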