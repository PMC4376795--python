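"""Finite-horizon Beta-Bernoulli two-armed bandit.

Each arm pays a fixed unit reward with an unknown stationary probability
q.  With a Beta(alpha, beta) prior the information state of an arm is its
reward/choice count pair (r, c); posterior pseudo-counts R = r + alpha,
C = c + alpha + beta give the posterior mean R/C, which is both the
expected immediate reward of sampling the arm and its rewarded-branch
transition probability.  The joint task is an undiscounted, finite-
horizon POMDP over the product of the two arms' count lattices, solved
exactly by backward induction; the FEV difference between a less-sampled
and a better-known arm is the exploration bonus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .core import SpecError, TaskSpec, ValueSolution, backward_induction

__all__ = [
    "BetaArmState",
    "BanditJointState",
    "posterior_mean",
    "arm_transition",
    "bandit_spec",
    "solve_bandit",
    "exploration_bonus",
    "scenario_eval",
    "parse_sequence",
    "heuristic_two_phase_value",
]


@dataclass(frozen=True, order=True)
class BetaArmState:
    """Counts-plus-prior sufficient statistics of one Bernoulli arm."""

    r: int = 0
    c: int = 0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise SpecError(f"prior pseudo-counts must be positive, got Beta({self.alpha}, {self.beta})")
        if not (0 <= self.r <= self.c):
            raise SpecError(f"need 0 <= rewards <= choices, got r={self.r}, c={self.c}")

    @property
    def R(self) -> float:
        return self.r + self.alpha

    @property
    def C(self) -> float:
        return self.c + self.alpha + self.beta

    def encode(self) -> str:
        return f"{self.r}/{self.c}"


@dataclass(frozen=True)
class BanditJointState:
    """Product information state over the two arms."""

    arm1: BetaArmState
    arm2: BetaArmState

    def arm(self, i: int) -> BetaArmState:
        if i == 1:
            return self.arm1
        if i == 2:
            return self.arm2
        raise SpecError(f"arm index must be 1 or 2, got {i}")

    def with_arm(self, i: int, new: BetaArmState) -> "BanditJointState":
        return BanditJointState(new, self.arm2) if i == 1 else BanditJointState(self.arm1, new)

    def encode(self) -> str:
        return f"{self.arm1.encode()}:{self.arm2.encode()}"


def posterior_mean(arm: BetaArmState) -> float:
    """Expected posterior reward probability (r + alpha)/(c + alpha + beta)."""
    return arm.R / arm.C


def arm_transition(arm: BetaArmState) -> list[tuple[BetaArmState, float]]:
    """Sampling outcome branches: rewarded with probability R/C, else not."""
    q = posterior_mean(arm)
    rewarded = replace(arm, r=arm.r + 1, c=arm.c + 1)
    unrewarded = replace(arm, c=arm.c + 1)
    return [(rewarded, q), (unrewarded, 1.0 - q)]


def bandit_spec(
    start: BanditJointState,
    horizon: int,
    reward_magnitude: float = 1.0,
) -> TaskSpec:
    """TaskSpec for the joint bandit from a given start state (gamma = 1)."""

    def actions(s: BanditJointState):
        return (1, 2)

    def reward(s: BanditJointState, a: int) -> float:
        return reward_magnitude * posterior_mean(s.arm(a))

    def transitions(s: BanditJointState, a: int):
        return [(s.with_arm(a, arm), p) for arm, p in arm_transition(s.arm(a))]

    return TaskSpec(
        actions=actions,
        reward=reward,
        transitions=transitions,
        discount=1.0,
        horizon=horizon,
        start=[start],
        name="stationary-bandit",
    )


#: the joint information space holds O(N^4) states; refuse horizons whose
#: lattice would not fit comfortably in memory
MAX_HORIZON = 120


def solve_bandit(
    priors: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0)),
    horizon: int = 8,
    start: BanditJointState | None = None,
    reward_magnitude: float = 1.0,
) -> ValueSolution:
    """Solve the two-armed bandit exactly over the reachable lattice.

    ``priors`` gives (alpha, beta) per arm; alternatively pass an explicit
    ``start`` joint state (mid-scenario counts).  The information lattice
    grows as the fourth power of the horizon, so horizons beyond
    ``MAX_HORIZON`` raise a resource error rather than exhausting memory.
    """
    if horizon > MAX_HORIZON:
        raise SpecError(
            f"horizon {horizon} would need ~{horizon**4 // 24:,} information states; "
            f"the supported maximum is {MAX_HORIZON}"
        )
    if start is None:
        (a1, b1), (a2, b2) = priors
        start = BanditJointState(BetaArmState(0, 0, a1, b1), BetaArmState(0, 0, a2, b2))
    return backward_induction(bandit_spec(start, horizon, reward_magnitude))


class _LayeredValues:
    """Vectorized backward induction over the joint count lattice.

    Layer k (trial t = k + 1) holds the states reachable after k extra
    samples from the start counts: (dc1, dr1, dr2) with dc2 = k - dc1,
    laid out contiguously per dc1 block, row-major in (dr1, dr2).  Heavy
    analytics (horizon sweeps, scenario replays) use this path; the
    generic solver remains the reference implementation and the two are
    equal by construction of the same recursion.
    """

    def __init__(self, start: BanditJointState, horizon: int, reward_magnitude: float = 1.0):
        self.start = start
        self.horizon = horizon
        self.m = reward_magnitude
        a1, a2 = start.arm1, start.arm2
        self.base = (a1.r, a1.c, a2.r, a2.c)
        self.priors = (a1.alpha, a1.beta, a2.alpha, a2.beta)
        self.u: list[np.ndarray] = [None] * horizon  # layer k utilities
        self._coords = [self._layer_coords(k) for k in range(horizon)]
        self._solve()

    @staticmethod
    def _layer_coords(k: int):
        sizes = np.array([(d + 1) * (k - d + 1) for d in range(k + 1)])
        off = np.concatenate([[0], np.cumsum(sizes)])
        dc1 = np.repeat(np.arange(k + 1), sizes)
        dr1 = np.concatenate([np.repeat(np.arange(d + 1), k - d + 1) for d in range(k + 1)])
        dr2 = np.concatenate([np.tile(np.arange(k - d + 1), d + 1) for d in range(k + 1)])
        return dc1, dr1, dr2, off

    def _q(self, k: int):
        """Posterior means of both arms across layer k."""
        dc1, dr1, dr2, _ = self._coords[k]
        r10, c10, r20, c20 = self.base
        al1, be1, al2, be2 = self.priors
        q1 = (r10 + dr1 + al1) / (c10 + dc1 + al1 + be1)
        q2 = (r20 + dr2 + al2) / (c20 + (k - dc1) + al2 + be2)
        return q1, q2

    def _succ_idx(self, k: int):
        """Successor indices in layer k+1 for both arms' outcome branches."""
        dc1, dr1, dr2, _ = self._coords[k]
        _, _, _, off1 = self._coords[k + 1]
        w1 = k + 1 - dc1          # dr2 width of block dc1+1 in layer k+1
        i1_up = off1[dc1 + 1] + (dr1 + 1) * w1 + dr2
        i1_dn = off1[dc1 + 1] + dr1 * w1 + dr2
        w2 = k + 2 - dc1          # dr2 width of block dc1 in layer k+1
        i2_up = off1[dc1] + dr1 * w2 + dr2 + 1
        i2_dn = off1[dc1] + dr1 * w2 + dr2
        return i1_up, i1_dn, i2_up, i2_dn

    def q_values(self, k: int):
        """(Q1, Q2, fev1, fev2) across layer k (gamma = 1)."""
        q1, q2 = self._q(k)
        if k == self.horizon - 1:
            fev1 = np.zeros_like(q1)
            fev2 = np.zeros_like(q2)
        else:
            u_next = self.u[k + 1]
            i1_up, i1_dn, i2_up, i2_dn = self._succ_idx(k)
            fev1 = q1 * u_next[i1_up] + (1.0 - q1) * u_next[i1_dn]
            fev2 = q2 * u_next[i2_up] + (1.0 - q2) * u_next[i2_dn]
        return self.m * q1 + fev1, self.m * q2 + fev2, fev1, fev2

    def _solve(self):
        for k in range(self.horizon - 1, -1, -1):
            quads = self.q_values(k)
            self.u[k] = np.maximum(quads[0], quads[1])

    def state_index(self, k: int, dc1: int, dr1: int, dr2: int) -> int:
        _, _, _, off = self._coords[k]
        return int(off[dc1] + dr1 * (k - dc1 + 1) + dr2)

    def at_state(self, k: int, dc1: int, dr1: int, dr2: int) -> dict:
        """IEV/FEV/Q for both arms at one state of layer k."""
        q1a, q2a, f1a, f2a = self.q_values(k)
        i = self.state_index(k, dc1, dr1, dr2)
        q1, q2 = self._q(k)
        return {
            "Q1": float(q1a[i]), "Q2": float(q2a[i]),
            "fev1": float(f1a[i]), "fev2": float(f2a[i]),
            "iev1": float(self.m * q1[i]), "iev2": float(self.m * q2[i]),
        }


def exploration_bonus(state: BanditJointState, horizon: int) -> float:
    """FEV(less-sampled arm) - FEV(more-sampled arm) at trial 1 of ``horizon``.

    With one trial remaining there is no future, so the bonus is 0.  The
    less-sampled arm is the one with the smaller choice count (posterior
    pseudo-count C on ties).
    """
    lv = _LayeredValues(state, horizon)
    vals = lv.at_state(0, 0, 0, 0)
    less_is_1 = (state.arm1.c, state.arm1.C) < (state.arm2.c, state.arm2.C)
    return (vals["fev1"] - vals["fev2"]) if less_is_1 else (vals["fev2"] - vals["fev1"])


_TOKEN = re.compile(r"^([12])([+-])$")


def parse_sequence(text: str) -> list[tuple[int, bool]]:
    """Parse a choice/outcome string like ``"1+ 1- 2+"``.

    Each token is the arm index followed by ``+`` (rewarded) or ``-``
    (unrewarded).  Malformed tokens raise ValueError with their 1-based
    position.
    """
    out = []
    for pos, tok in enumerate(text.split(), start=1):
        m = _TOKEN.match(tok)
        if not m:
            raise ValueError(f"malformed choice/outcome token {tok!r} at position {pos}")
        out.append((int(m.group(1)), m.group(2) == "+"))
    return out


def scenario_eval(
    sequence: str | list[tuple[int, bool]],
    horizon: int,
    priors: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0)),
) -> list[dict]:
    """Replay a fixed (possibly suboptimal) choice/outcome sequence.

    Returns one record per trial (including the trial after the last
    outcome, while t <= horizon) with the state and both arms' Q, IEV and
    FEV under the exact solution of the full-horizon model.
    """
    seq = parse_sequence(sequence) if isinstance(sequence, str) else list(sequence)
    if len(seq) >= horizon:
        raise ValueError(f"sequence of {len(seq)} outcomes does not fit inside horizon {horizon}")
    (a1, b1), (a2, b2) = priors
    root = BanditJointState(BetaArmState(0, 0, a1, b1), BetaArmState(0, 0, a2, b2))
    lv = _LayeredValues(root, horizon)
    records = []
    dc1 = dr1 = dr2 = 0
    state = root
    for t in range(1, len(seq) + 2):
        rec = {"trial": t, "state": state.encode()}
        rec.update(lv.at_state(t - 1, dc1, dr1, dr2))
        records.append(rec)
        if t > len(seq):
            break
        arm, rewarded = seq[t - 1]
        if arm == 1:
            dc1 += 1
            dr1 += int(rewarded)
        else:
            dr2 += int(rewarded)
        cur = state.arm(arm)
        state = state.with_arm(arm, replace(cur, r=cur.r + int(rewarded), c=cur.c + 1))
    return records


def heuristic_two_phase_value(
    p_known: float,
    p_hi: float,
    p_lo: float,
    n_probe: int,
    n_total: int,
) -> dict[str, float]:
    """Two-phase probe-then-commit heuristic for the exploration bonus.

    A known arm pays with probability ``p_known``.  The alternative is
    probed for ``n_probe`` of the ``n_total`` remaining trials and turns
    out (equiprobably) to pay with ``p_hi`` (then kept for the whole
    horizon) or ``p_lo`` (then abandoned for the known arm).  Returns the
    always-stay value, both branch values, their average, and the excess
    of that average over staying — the exploration bonus.
    """
    for name, p in (("p_known", p_known), ("p_hi", p_hi), ("p_lo", p_lo)):
        if not 0.0 <= p <= 1.0:
            raise SpecError(f"{name} must lie in [0, 1], got {p}")
    if not 0 < n_probe <= n_total:
        raise SpecError(f"need 0 < n_probe <= n_total, got {n_probe}, {n_total}")
    stay_value = p_known * n_total
    branch_hi = p_hi * n_total
    branch_lo = p_lo * n_probe + p_known * (n_total - n_probe)
    average = 0.5 * (branch_hi + branch_lo)
    return {
        "stay_value": stay_value,
        "branch_hi": branch_hi,
        "branch_lo": branch_lo,
        "average": average,
        "bonus": average - stay_value,
    }
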