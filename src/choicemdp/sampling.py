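"""Foraging-by-sampling: accept the offered gamble pair or pay to redraw.

Each bout fixes six gambles of known magnitudes; every trial shows an
unordered pair (15 possible), and the forager accepts — moving to a
decision stage where each gamble's payout probability, independently
uniform on [0.2, 0.9], is revealed and the better product is taken — or
pays a sampling cost for a fresh uniform draw of one of the 15 pairs.
The value of a pair is E[max(g1 p1, g2 p2)]: the probabilities operate
under the max because the decision stage picks the better revealed
gamble.  A finite-horizon (60 trials) undiscounted MDP over the 15 pair
states is solved by backward induction; with enough trials left the
resample value is offer-independent, so the policy is simply "accept
when the current pair beats the constant value of sampling on".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import SpecError, TaskSpec, ValueSolution, backward_induction

__all__ = [
    "SamplingParams",
    "pair_states",
    "pair_value",
    "sampling_spec",
    "solve_sampling",
    "policy_trace",
]

ACCEPT = "accept"
SAMPLE = "sample"


@dataclass(frozen=True)
class SamplingParams:
    """Gamble magnitudes, sampling cost, horizon and probability range."""

    gambles: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0, 130.0)
    c_sample: float = -7.0
    horizon: int = 60
    p_range: tuple[float, float] = (0.2, 0.9)
    quadrature_points: int = 200

    def __post_init__(self):
        if len(set(self.gambles)) != 6 or min(self.gambles) < 0:
            raise SpecError("need 6 distinct nonnegative gamble magnitudes")
        if self.horizon < 1:
            raise SpecError("horizon must be >= 1")
        a, b = self.p_range
        if not (0.0 <= a <= b <= 1.0):
            raise SpecError(f"probability range must satisfy 0 <= a <= b <= 1, got {self.p_range}")


#: magnitudes used in the task itself: 20..130 in steps of 10, of which six
#: are sampled per bout
TASK_MAGNITUDE_POOL = tuple(float(g) for g in range(20, 131, 10))


def pair_states(params: SamplingParams) -> list[tuple[float, float]]:
    """The 15 unordered gamble pairs (sampling without replacement)."""
    return [tuple(sorted(p)) for p in combinations(sorted(params.gambles), 2)]


def pair_value(g1: float, g2: float, p_range: tuple[float, float] = (0.2, 0.9), n: int = 200) -> float:
    """E[max(g1 p1, g2 p2)] with p1, p2 independent uniform on [a, b].

    The printed double integral is normalized by (b - a)^2 so the result
    is an expectation on the points scale.  Midpoint product quadrature
    on an n x n grid; the integrand is bilinear away from the max kink,
    so n = 200 gives ~1e-6 relative accuracy.  A degenerate range a = b
    evaluates the max at the single point.
    """
    if g1 < 0 or g2 < 0:
        raise SpecError("gamble magnitudes must be nonnegative")
    a, b = p_range
    if not (0.0 <= a <= b <= 1.0):
        raise SpecError(f"invalid probability range {p_range}")
    if a == b:
        return float(max(g1 * a, g2 * a))
    p = a + (b - a) * (np.arange(n) + 0.5) / n
    v1 = g1 * p
    v2 = g2 * p
    m = np.maximum(v1[:, None], v2[None, :])
    return float(m.mean())


def sampling_spec(params: SamplingParams) -> TaskSpec:
    """TaskSpec over the 15 pair states; accept is forced on the last trial."""
    pairs = pair_states(params)
    if len(pairs) != 15:
        raise SpecError(f"expected 15 pair states, got {len(pairs)}")
    values = {s: pair_value(*s, params.p_range, params.quadrature_points) for s in pairs}
    p_next = 1.0 / len(pairs)

    def actions(s):
        return (ACCEPT, SAMPLE)

    def terminal_actions(s):
        return (ACCEPT,)

    def reward(s, a):
        return values[s] if a == ACCEPT else 0.0

    def cost(s, a):
        return params.c_sample if a == SAMPLE else 0.0

    def transitions(s, a):
        if a == ACCEPT:
            return []  # accepting ends the foraging bout
        return [(j, p_next) for j in pairs]

    return TaskSpec(
        actions=actions,
        reward=reward,
        cost=cost,
        transitions=transitions,
        discount=1.0,
        horizon=params.horizon,
        start=pairs,
        terminal_actions=terminal_actions,
        name="sampling-foraging",
    )


def solve_sampling(params: SamplingParams = SamplingParams()) -> ValueSolution:
    """Backward induction over pairs x trials (accept forced at the horizon)."""
    return backward_induction(sampling_spec(params))


def policy_trace(
    offers: list[tuple[float, float]] | None,
    params: SamplingParams = SamplingParams(),
    seed: int | None = None,
    solution: ValueSolution | None = None,
) -> list[dict]:
    """Replay an offer sequence (or draw one with ``seed``) against the policy.

    Returns per-trial records with both action values and the decision;
    stops at (and includes) the accepted offer or the forced horizon.
    """
    pairs = pair_states(params)
    sol = solve_sampling(params) if solution is None else solution
    rng = np.random.default_rng(seed)
    records = []
    for t in range(1, params.horizon + 1):
        if offers is not None:
            if t > len(offers):
                break
            offer = tuple(sorted(offers[t - 1]))
            if offer not in pairs:
                raise SpecError(f"unknown gamble pair {offer!r} at trial {t}")
        else:
            offer = pairs[rng.integers(len(pairs))]
        qv = sol.action_values(t, offer)
        accept = SAMPLE not in qv or qv[ACCEPT] >= qv[SAMPLE]
        records.append(
            {
                "trial": t,
                "offer": offer,
                "Q_accept": qv[ACCEPT],
                "Q_sample": qv.get(SAMPLE),
                "decision": ACCEPT if accept else SAMPLE,
            }
        )
        if accept:
            break
    return records
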