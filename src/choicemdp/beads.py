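"""Ideal observer for the beads (urn) information-sampling task.

Beads are drawn one at a time from one of two urns; the majority urn
holds a fraction ``q`` of its own colour.  After each draw one can guess
blue, guess orange, or pay a small cost to draw again, up to
``max_draws`` beads, after which a guess is forced.  The state is the
draw count and blue count (n_d, n_b) — the sufficient statistics — and
with equal urn priors the blue-urn posterior has the logistic closed
form p_b = 1/(1 + (q/(1-q))^(n_d - 2 n_b)).  Guessing terminates the
trial (zero FEV); drawing buys information (its value is all FEV).  The
task is an undiscounted finite-horizon POMDP solved by backward
induction over the draw lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import SpecError, TaskSpec, ValueSolution, backward_induction

__all__ = [
    "BeadsParams",
    "BeadsState",
    "GUESS_BLUE",
    "GUESS_ORANGE",
    "DRAW",
    "posterior_blue",
    "beads_action_values",
    "beads_spec",
    "solve_beads",
    "optimal_stop_trial",
    "parse_beads",
]

GUESS_BLUE = "blue"
GUESS_ORANGE = "orange"
DRAW = "draw"


@dataclass(frozen=True)
class BeadsParams:
    """Task constants: urn composition, horizon and payoffs."""

    q: float = 0.6            # majority-urn bead fraction
    max_draws: int = 12
    c_correct: float = 1.0
    c_error: float = 0.0
    c_sample: float = -0.005  # cost per draw

    def __post_init__(self):
        if not (0.5 <= self.q < 1.0):
            raise SpecError(f"majority fraction must lie in [0.5, 1), got {self.q}")
        if self.q == 0.5:
            warnings.warn("q = 0.5 makes every bead uninformative (posterior stays 0.5)", stacklevel=3)
        if self.max_draws < 1:
            raise SpecError("max_draws must be >= 1")


@dataclass(frozen=True)
class BeadsState:
    """Draw count and blue count."""

    n_d: int = 0
    n_b: int = 0

    def __post_init__(self):
        if not (0 <= self.n_b <= self.n_d):
            raise SpecError(f"need 0 <= n_b <= n_d, got n_b={self.n_b}, n_d={self.n_d}")


def posterior_blue(state: BeadsState, q: float) -> float:
    """P(blue urn | draws) = 1/(1 + (q/(1-q))^(n_d - 2 n_b)), equal priors."""
    ratio = q / (1.0 - q)
    return 1.0 / (1.0 + ratio ** (state.n_d - 2 * state.n_b))


def _draw_probs(state: BeadsState, q: float) -> tuple[float, float]:
    """(P(next bead blue), P(next bead orange)) under the current posterior."""
    p_b = posterior_blue(state, q)
    p_o = 1.0 - p_b
    p_blue_bead = q * p_b + (1.0 - q) * p_o
    return p_blue_bead, 1.0 - p_blue_bead


def beads_spec(params: BeadsParams) -> TaskSpec:
    """TaskSpec over the (n_d, n_b) lattice; drawing is illegal at the horizon."""

    def actions(s: BeadsState):
        if s.n_d >= params.max_draws:
            return (GUESS_BLUE, GUESS_ORANGE)
        return (GUESS_BLUE, GUESS_ORANGE, DRAW)

    def reward(s: BeadsState, a: str) -> float:
        if a == DRAW:
            return 0.0
        p_b = posterior_blue(s, params.q)
        p_correct = p_b if a == GUESS_BLUE else 1.0 - p_b
        return params.c_correct * p_correct + params.c_error * (1.0 - p_correct)

    def cost(s: BeadsState, a: str) -> float:
        return params.c_sample if a == DRAW else 0.0

    def transitions(s: BeadsState, a: str):
        if a != DRAW:
            return []  # guessing terminates the trial
        if s.n_d >= params.max_draws:
            raise SpecError(f"draw requested at the {params.max_draws}-bead horizon (state {s})")
        pb, po = _draw_probs(s, params.q)
        return [(BeadsState(s.n_d + 1, s.n_b + 1), pb), (BeadsState(s.n_d + 1, s.n_b), po)]

    return TaskSpec(
        actions=actions,
        reward=reward,
        cost=cost,
        transitions=transitions,
        discount=1.0,
        horizon=params.max_draws + 1,
        start=[BeadsState(0, 0)],
        name="beads",
    )


def beads_action_values(state: BeadsState, params: BeadsParams, u_next) -> dict[str, float]:
    """Q for {guess blue, guess orange, draw} given next-lattice utilities.

    ``u_next`` maps (n_d + 1)-row states to utilities; pass None for the
    forced-guess horizon row.  Guesses carry zero FEV by construction.
    """
    spec = beads_spec(params)
    acts = (GUESS_BLUE, GUESS_ORANGE) if state.n_d >= params.max_draws else (GUESS_BLUE, GUESS_ORANGE, DRAW)
    from .core import q_decompose

    decomp = q_decompose(spec, u_next, state.n_d + 1, state, acts)
    return {a: q for a, (_i, _f, q) in decomp.items()}


def solve_beads(params: BeadsParams = BeadsParams()) -> ValueSolution:
    """Backward induction from the forced guess at n_d = max_draws to n_d = 0.

    Trial t holds the lattice row n_d = t - 1, so the solution is keyed
    by (n_d + 1, state).
    """
    return backward_induction(beads_spec(params))


def parse_beads(sequence: str) -> list[bool]:
    """Parse a bead string over {B, O} into per-draw is-blue flags."""
    out = []
    for pos, ch in enumerate(sequence.strip().upper(), start=1):
        if ch in " ,":
            continue
        if ch not in "BO":
            raise ValueError(f"invalid bead {ch!r} at position {pos} (expected B or O)")
        out.append(ch == "B")
    return out


def optimal_stop_trial(
    sequence: str | list[bool],
    params: BeadsParams = BeadsParams(),
    solution: ValueSolution | None = None,
) -> tuple[int | None, str | None]:
    """First draw index at which guessing beats drawing again, plus the guess.

    Walks the bead sequence through the solved lattice; after seeing bead
    k the state is (n_d = k, n_b); returns the first k where
    max(guess values) > Q(draw), or (None, None) if the decision is
    forced only at the horizon.
    """
    beads = parse_beads(sequence) if isinstance(sequence, str) else list(sequence)
    if len(beads) > params.max_draws:
        raise ValueError(f"sequence of {len(beads)} beads exceeds max_draws={params.max_draws}")
    sol = solve_beads(params) if solution is None else solution
    n_b = 0
    for k, is_blue in enumerate(beads, start=1):
        n_b += int(is_blue)
        s = BeadsState(k, n_b)
        t = k + 1
        qv = sol.action_values(t, s)
        best_guess = max(qv[GUESS_BLUE], qv[GUESS_ORANGE])
        # strict preference for guessing, with float-noise guard so an
        # exact tie (possible when C_s = 0) counts as drawing on
        if DRAW not in qv or best_guess > qv[DRAW] + 1e-12:
            urn = GUESS_BLUE if qv[GUESS_BLUE] >= qv[GUESS_ORANGE] else GUESS_ORANGE
            if DRAW in qv:
                return k, urn
            return None, urn  # forced at the horizon, never strictly better
    return None, None
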