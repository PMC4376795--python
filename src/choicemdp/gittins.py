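"""Gittins (dynamic allocation) indices for Beta-Bernoulli arms.

A discounted stationary multi-armed bandit separates into one problem
per arm: each arm state i gets a scalar index, and ranking the current
indices yields the optimal policy.  The index is computed with the
restart-in-state formulation: on the single arm's count lattice every
state offers either *continue* (sample the arm from here) or *restart*
(jump back to state i and continue from there), and the index of i is
the fixed point value u(i), found by value iteration.  Indices are on
the discounted total-value scale — a certainly-rewarding unit arm has
index 1/(1 - gamma) — but they are not value estimates of the joint
problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import ConvergenceError, SpecError
from .stationary import BanditJointState, BetaArmState, posterior_mean

__all__ = ["GittinsQuery", "gittins_index", "index_policy", "index_lattice"]


@dataclass(frozen=True)
class GittinsQuery:
    """Arm state plus discount and single-arm lattice truncation depth."""

    arm: BetaArmState
    gamma: float
    depth: int = 200
    tol: float = 1e-9
    max_iter: int = 100_000

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise SpecError(
                f"Gittins indices require gamma < 1 (got {self.gamma}); "
                "infinite-horizon undiscounted indices cannot be obtained"
            )
        if self.depth < 1:
            raise SpecError("truncation depth must be >= 1")


class _Lattice:
    """Single-arm count lattice rooted at the queried state.

    The reachable states of an arm at posterior counts (R0, C0) are
    (R0 + dr, C0 + dc) with 0 <= dr <= dc <= depth; the restart action
    returns to the root.  States at the cap dc = depth are absorbing
    with the known-arm value (R/C)/(1 - gamma): by then the posterior is
    sharp enough that further learning is worth little, and the cap
    keeps the restart problem finite.
    """

    def __init__(self, R0: float, C0: float, depth: int):
        states = [(dr, dc) for dc in range(depth + 1) for dr in range(dc + 1)]
        self.index = {s: i for i, s in enumerate(states)}
        dr = np.array([s[0] for s in states], dtype=float)
        dc = np.array([s[1] for s in states], dtype=float)
        self.q = (R0 + dr) / (C0 + dc)
        self.capped = np.array([s[1] >= depth for s in states])
        up = np.zeros(len(states), dtype=np.int64)
        dn = np.zeros(len(states), dtype=np.int64)
        for i, (dri, dci) in enumerate(states):
            if dci < depth:
                up[i] = self.index[(dri + 1, dci + 1)]
                dn[i] = self.index[(dri, dci + 1)]
        self.up, self.dn = up, dn

    def continue_values(self, u: np.ndarray, gamma: float) -> np.ndarray:
        cont = self.q + gamma * (self.q * u[self.up] + (1.0 - self.q) * u[self.dn])
        return np.where(self.capped, self.q / (1.0 - gamma), cont)


@lru_cache(maxsize=100_000)
def _index_cached(R0: float, C0: float, gamma: float, depth: int, tol: float, max_iter: int) -> float:
    lat = _Lattice(R0, C0, depth)
    u = lat.q / (1.0 - gamma)  # start from the known-arm values
    for _ in range(max_iter):
        cont = lat.continue_values(u, gamma)
        u_new = np.maximum(cont, cont[0])  # index 0 is the root state
        change = float(np.max(np.abs(u_new - u)))
        u = u_new
        if change < tol:
            return float(u[0])
    raise ConvergenceError(
        f"restart value iteration for counts (R={R0}, C={C0}) did not converge (last change {change:.3e})"
    )


def gittins_index(query: GittinsQuery) -> float:
    """Gittins index of a Beta-Bernoulli arm state (restart fixed point).

    Depends only on the single arm's posterior counts and the discount —
    never on any other arm — so indices computed once serve any number
    of arms.  Results are cached per (R, C, gamma, truncation).
    """
    a = query.arm
    return _index_cached(a.R, a.C, query.gamma, query.depth, query.tol, query.max_iter)


def index_policy(state: BanditJointState, gamma: float, depth: int = 200) -> int:
    """Arm with the largest Gittins index (lowest arm index on ties)."""
    i1 = gittins_index(GittinsQuery(state.arm1, gamma, depth))
    i2 = gittins_index(GittinsQuery(state.arm2, gamma, depth))
    return 1 if i1 >= i2 else 2


def index_lattice(gamma: float, c_max_states: int, alpha: float = 1.0, beta: float = 1.0, depth: int = 200) -> list[dict]:
    """Indices for every (r, c) with c < ``c_max_states`` (CSV-ready rows)."""
    rows = []
    for c in range(c_max_states):
        for r in range(c + 1):
            arm = BetaArmState(r, c, alpha, beta)
            rows.append(
                {
                    "r": r,
                    "c": c,
                    "posterior_mean": posterior_mean(arm),
                    "index": gittins_index(GittinsQuery(arm, gamma, depth)),
                }
            )
    return rows
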