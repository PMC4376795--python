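"""Patch-leaving foraging as an explicit-time infinite-horizon MDP.

Time advances in 100 ms steps.  At a choice state (current juice level,
current travel delay) the forager either *stays* — entering a 400 ms
reward chain whose last state delivers the current juice amount, after
which the patch is depleted by one 20 uL unit — or *leaves* — entering
a travel chain of the currently known delay, arriving at a fresh patch
whose travel delay is resampled uniformly from the 11 possible values
(500..10500 ms in 1000 ms steps).  Both reward and travel chains
terminate in a 1500 ms inter-trial interval that leads back to a choice
state.  The only stochastic transition is the new travel delay.

Discounted (gamma < 1), the value of leaving shrinks with the delay
ahead, so longer delays mean staying down to lower juice levels —
the marginal-value-theorem pattern.  Undiscounted (gamma = 1,
average-reward/differential solving) the current delay is paid exactly
once whichever action is taken now, so the stay-minus-leave value
difference is identical across delays: finite travel times cannot
matter to an infinite undiscounted horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpecError, TaskSpec, ValueSolution, value_iteration

__all__ = [
    "PatchParams",
    "build_patch_mdp",
    "solve_patch",
    "PatchSolution",
    "time_in_patch",
    "simulate_residence",
]

STAY = "stay"
LEAVE = "leave"
WAIT = "wait"


@dataclass(frozen=True)
class PatchParams:
    """Chain lengths in 100 ms steps, juice in 20 uL units."""

    iti_steps: int = 15                    # 1500 ms
    reward_steps: int = 4                  # 400 ms
    travel_steps: tuple[int, ...] = tuple(range(5, 106, 10))  # 500..10500 ms
    juice_reset: int = 10                  # fresh-patch juice, units
    juice_max: int = 15                    # configurable cap, units
    juice_decrement: int = 1               # per stay choice

    def __post_init__(self):
        if min(self.iti_steps, self.reward_steps, min(self.travel_steps)) < 1:
            raise SpecError("all chain lengths must be >= 1")
        if not (0 < self.juice_reset <= self.juice_max):
            raise SpecError("need 0 < juice_reset <= juice_max")

    @property
    def n_delays(self) -> int:
        return len(self.travel_steps)

    def delay_ms(self, d: int) -> int:
        return self.travel_steps[d] * 100


def build_patch_mdp(params: PatchParams) -> TaskSpec:
    """Explicit-state TaskSpec; only choice states offer two actions.

    States: ``('choice', j, d)``; ``('reward', k, j, d)`` with the
    reward j delivered at k = reward_steps; ``('iti', k, j, d)`` leading
    to ``('choice', j, d)``; ``('travel', k, d, d_new)`` traversing the
    old delay d before the fresh patch with delay d_new.
    """
    nd = params.n_delays
    juices = range(params.juice_reset + 1)
    states: list = []
    for d in range(nd):
        for j in juices:
            states.append(("choice", j, d))
            for k in range(1, params.reward_steps + 1):
                states.append(("reward", k, j, d))
            for k in range(1, params.iti_steps + 1):
                states.append(("iti", k, j, d))
        for d_new in range(nd):
            for k in range(1, params.travel_steps[d] + 1):
                states.append(("travel", k, d, d_new))

    def actions(s):
        return (STAY, LEAVE) if s[0] == "choice" else (WAIT,)

    def reward(s, a):
        # the final reward-chain state delivers the current juice amount
        if s[0] == "reward" and s[1] == params.reward_steps:
            return float(s[2])
        return 0.0

    def transitions(s, a):
        kind = s[0]
        if kind == "choice":
            _, j, d = s
            if a == STAY:
                return [(("reward", 1, j, d), 1.0)]
            if a == LEAVE:
                p = 1.0 / nd
                return [(("travel", 1, d, d_new), p) for d_new in range(nd)]
            raise SpecError(f"unknown action {a!r} in state {s!r}")
        if kind == "reward":
            _, k, j, d = s
            if k < params.reward_steps:
                return [(("reward", k + 1, j, d), 1.0)]
            j_next = max(j - params.juice_decrement, 0)
            return [(("iti", 1, j_next, d), 1.0)]
        if kind == "iti":
            _, k, j, d = s
            if k < params.iti_steps:
                return [(("iti", k + 1, j, d), 1.0)]
            return [(("choice", j, d), 1.0)]
        if kind == "travel":
            _, k, d, d_new = s
            if k < params.travel_steps[d]:
                return [(("travel", k + 1, d, d_new), 1.0)]
            return [(("iti", 1, params.juice_reset, d_new), 1.0)]
        raise SpecError(f"unknown state {s!r}")

    return TaskSpec(
        actions=actions,
        reward=reward,
        transitions=transitions,
        discount=1.0,  # overridden per solve
        states=states,
        name="patch-foraging",
    )


@dataclass
class PatchSolution:
    """Stay-minus-leave surface and indifference frontier at choice states."""

    params: PatchParams
    gamma: float
    solution: ValueSolution
    dq: np.ndarray          # (juice, delay) -> Q(stay) - Q(leave)

    def frontier(self) -> list[int | None]:
        """Per delay, the lowest juice level at which staying is chosen."""
        out = []
        for d in range(self.params.n_delays):
            stays = [j for j in range(self.params.juice_reset + 1) if self.dq[j, d] >= 0.0]
            out.append(min(stays) if stays else None)
        return out


def solve_patch(
    params: PatchParams = PatchParams(),
    gamma: float = 0.9998,
    tol: float | None = None,
    max_iter: int = 300_000,
) -> PatchSolution:
    """Value-iterate the patch MDP and return the stay/leave surface.

    gamma = 1 routes to span-criterion differential solving (damped
    operator); the per-step default gamma of 0.9998 corresponds to a
    ~8-minute discounting time constant on the 100 ms step.
    """
    spec = build_patch_mdp(params)
    spec.discount = gamma
    if gamma == 1.0:
        sol = value_iteration(spec, tol=1e-11 if tol is None else tol, criterion="span", max_iter=max_iter)
    else:
        sol = value_iteration(spec, tol=2e-4 if tol is None else tol, criterion="max-norm", max_iter=max_iter)
    dq = np.zeros((params.juice_reset + 1, params.n_delays))
    for j in range(params.juice_reset + 1):
        for d in range(params.n_delays):
            s = ("choice", j, d)
            dq[j, d] = sol.Q[(0, s, STAY)] - sol.Q[(0, s, LEAVE)]
    return PatchSolution(params=params, gamma=gamma, solution=sol, dq=dq)


def time_in_patch(ps: PatchSolution, delay: int) -> int:
    """Stay choices before leaving a fresh patch under the greedy policy.

    Deterministic: juice runs from the reset level down to the policy's
    leave point for this delay.  Ties choose stay (first action).
    """
    j = ps.params.juice_reset
    count = 0
    while j >= 0:
        if ps.dq[j, delay] < 0.0:
            return count
        count += 1
        if j == 0:
            raise SpecError(
                f"policy never leaves at delay {delay} (gamma={ps.gamma}); residence is unbounded"
            )
        j -= ps.params.juice_decrement
    return count


def simulate_residence(ps: PatchSolution, delay: int, max_steps: int = 100) -> int:
    """Forward-simulate the greedy policy from a fresh patch; count stays."""
    sol = ps.solution
    j, d = ps.params.juice_reset, delay
    count = 0
    for _ in range(max_steps):
        s = ("choice", j, d)
        if sol.chosen(0, s) == LEAVE:
            return count
        count += 1
        j = max(j - ps.params.juice_decrement, 0)
    raise SpecError(f"no leave within {max_steps} choice steps at delay {delay}")
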