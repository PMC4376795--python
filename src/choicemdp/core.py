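"""Exact dynamic-programming engines shared by all task modules.

Two solution regimes are supported:

* finite horizon — :func:`backward_induction` over the reachable state
  layers, trials indexed 1..N with t=N the final decision trial (an action
  is still taken on trial N; its value has no future component because no
  further choice follows);
* infinite horizon — :func:`value_iteration`, discounted (max-norm
  stopping) or undiscounted/average-reward (span stopping on differential
  values, with the average reward per stage subtracted out).

Every action value is stored as the sum of its immediate expected value
(IEV, reward plus cost-to-sample) and its future expected value (FEV, the
discount-weighted expectation of successor utilities), so the trade-off
that drives choice in each task can be read off directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np

State = Hashable
Action = Hashable

__all__ = [
    "TaskSpec",
    "ValueSolution",
    "SpecError",
    "ConvergenceError",
    "backward_induction",
    "value_iteration",
    "q_decompose",
    "greedy_policy",
]

#: transition probabilities must sum to 1 within this slack
_PROB_TOL = 1e-12


class SpecError(ValueError):
    """A task specification violates one of its structural invariants."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its stopping criterion."""


def _zero_cost(s: State, a: Action) -> float:
    return 0.0


@dataclass
class TaskSpec:
    """Declarative description of a (PO)MDP over opaque hashable states.

    Parameters
    ----------
    actions
        Callable ``actions(s)`` returning the nonempty action sequence
        available in state ``s``.  Order matters: the default tie rule
        picks the first (lowest-index) maximizer.
    reward
        ``reward(s, a)`` — expected immediate reward, task units.
    transitions
        ``transitions(s, a)`` — sequence of ``(successor, probability)``
        pairs.  An empty sequence marks a terminating action (zero FEV).
    cost
        ``cost(s, a)`` — cost-to-sample, typically <= 0; defaults to 0.
    discount
        gamma in (0, 1]; gamma = 1 is only legal for finite horizons or
        span-criterion (average-reward) value iteration.
    horizon
        positive integer for finite-horizon tasks, or ``"infinite"``.
    start
        iterable of start states; required by the finite-horizon solver,
        which enumerates reachable layers lazily from here.
    states
        explicit state list; required by value iteration.
    terminal_actions
        optional ``terminal_actions(s)`` overriding the action set on the
        final trial t = N (e.g. a forced accept when sampling ends).
    """

    actions: Callable[[State], Sequence[Action]]
    reward: Callable[[State, Action], float]
    transitions: Callable[[State, Action], Sequence[tuple[State, float]]]
    cost: Callable[[State, Action], float] = _zero_cost
    discount: float = 1.0
    horizon: int | str = "infinite"
    start: Iterable[State] | None = None
    states: Sequence[State] | None = None
    terminal_actions: Callable[[State], Sequence[Action]] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.discount <= 1.0):
            raise SpecError(f"discount must lie in (0, 1], got {self.discount}")
        if self.horizon != "infinite":
            if not isinstance(self.horizon, int) or self.horizon < 1:
                raise SpecError(f"horizon must be a positive integer or 'infinite', got {self.horizon!r}")

    def checked_transitions(self, s: State, a: Action) -> list[tuple[State, float]]:
        """Transitions for (s, a) with normalization asserted."""
        trans = list(self.transitions(s, a))
        if not trans:
            return trans
        total = 0.0
        for j, p in trans:
            if p < -_PROB_TOL:
                raise SpecError(f"negative transition probability {p} for state {s!r}, action {a!r}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise SpecError(
                f"transition probabilities for state {s!r}, action {a!r} sum to {total}, not 1"
            )
        return trans


@dataclass
class ValueSolution:
    """Utilities, decomposed action values and greedy policy of a solved task.

    Finite-horizon solutions are keyed by ``(t, state)`` with trials
    1-based; infinite-horizon solutions use the fixed key ``t = 0``.
    For average-reward (gamma = 1, span criterion) solutions ``u`` holds
    differential values and ``meta['gain']`` the average reward per stage.
    """

    u: dict = field(default_factory=dict)
    Q: dict = field(default_factory=dict)
    iev: dict = field(default_factory=dict)
    fev: dict = field(default_factory=dict)
    policy: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def utility(self, t: int, s: State) -> float:
        try:
            return self.u[(t, s)]
        except KeyError:
            raise LookupError(f"no utility stored for trial {t}, state {s!r}") from None

    def action_value(self, t: int, s: State, a: Action) -> float:
        try:
            return self.Q[(t, s, a)]
        except KeyError:
            raise LookupError(f"no action value stored for trial {t}, state {s!r}, action {a!r}") from None

    def action_values(self, t: int, s: State) -> dict[Action, float]:
        out = {a: q for (tt, ss, a), q in self.Q.items() if tt == t and ss == s}
        if not out:
            raise LookupError(f"no action values stored for trial {t}, state {s!r}")
        return out

    def future_value(self, t: int, s: State, a: Action) -> float:
        try:
            return self.fev[(t, s, a)]
        except KeyError:
            raise LookupError(f"no FEV stored for trial {t}, state {s!r}, action {a!r}") from None

    def chosen(self, t: int, s: State) -> Action:
        try:
            return self.policy[(t, s)]
        except KeyError:
            raise LookupError(f"no policy stored for trial {t}, state {s!r}") from None


def q_decompose(
    spec: TaskSpec,
    u_next: Mapping[State, float] | None,
    t: int,
    s: State,
    actions: Sequence[Action] | None = None,
) -> dict[Action, tuple[float, float, float]]:
    """Per-action (IEV, FEV, Q) at state ``s`` given next-trial utilities.

    ``u_next=None`` marks a terminal trial: FEV is 0 for every action
    because no choice follows.  Otherwise ``u_next`` must cover every
    successor; a missing one raises :class:`LookupError` naming it.
    """
    acts = list(self_actions(spec, s) if actions is None else actions)
    if not acts:
        raise SpecError(f"empty action set for state {s!r}")
    out: dict[Action, tuple[float, float, float]] = {}
    for a in acts:
        iev = spec.reward(s, a) + spec.cost(s, a)
        fev = 0.0
        if u_next is not None:
            for j, p in spec.checked_transitions(s, a):
                try:
                    uj = u_next[j]
                except KeyError:
                    raise LookupError(
                        f"missing successor utility for state {j!r} (from state {s!r}, action {a!r}, trial {t})"
                    ) from None
                fev += p * uj
            fev *= spec.discount
        out[a] = (iev, fev, iev + fev)
    return out


def self_actions(spec: TaskSpec, s: State) -> Sequence[Action]:
    acts = spec.actions(s)
    if not acts:
        raise SpecError(f"empty action set for state {s!r}")
    return acts


def _pick(acts: Sequence[Action], qvals: Mapping[Action, float], tie_rule: str, rng) -> Action:
    """argmax with documented tie handling (ties = exact float equality)."""
    best = max(qvals[a] for a in acts)
    winners = [a for a in acts if qvals[a] == best]
    if len(winners) == 1 or tie_rule == "first":
        return winners[0]
    if tie_rule == "random":
        return winners[rng.integers(len(winners))]
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def greedy_policy(
    q_table: Mapping[tuple[int, State, Action], float],
    tie_rule: str = "first",
    seed: int | None = None,
) -> dict[tuple[int, State], Action]:
    """Deterministic action per (t, s) from a Q table.

    ``tie_rule='first'`` (default) picks the lowest-index action among
    exact-tied maximizers, where index is insertion order in the table;
    ``tie_rule='random'`` breaks ties with a seeded generator and is
    reproducible for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    grouped: dict[tuple[int, State], list[Action]] = {}
    qvals: dict[tuple[int, State], dict[Action, float]] = {}
    for (t, s, a), q in q_table.items():
        grouped.setdefault((t, s), []).append(a)
        qvals.setdefault((t, s), {})[a] = q
    policy = {}
    for key, acts in grouped.items():
        if not acts:
            raise SpecError(f"empty action set for {key!r}")
        policy[key] = _pick(acts, qvals[key], tie_rule, rng)
    return policy


def reachable_layers(spec: TaskSpec, horizon: int) -> list[list[State]]:
    """States reachable on each trial 1..N from the start set (index 0 unused)."""
    if spec.start is None:
        raise SpecError("finite-horizon solving requires start states")
    layers: list[list[State]] = [[] for _ in range(horizon + 1)]
    layer = list(dict.fromkeys(spec.start))
    layers[1] = layer
    for t in range(1, horizon):
        nxt: dict[State, None] = {}
        for s in layer:
            for a in self_actions(spec, s):
                for j, _p in spec.checked_transitions(s, a):
                    nxt[j] = None
        layer = list(nxt)
        layers[t + 1] = layer
    return layers


def backward_induction(spec: TaskSpec, tie_rule: str = "first", seed: int | None = None) -> ValueSolution:
    """Solve a finite-horizon task exactly by backward induction.

    Utilities on the final trial t = N are the best immediate value (no
    future term); for t < N the Bellman recursion fills u, Q, IEV, FEV
    and the greedy policy over every reachable (t, state).
    """
    if spec.horizon == "infinite":
        raise SpecError("backward induction requires a finite horizon")
    n = int(spec.horizon)
    rng = np.random.default_rng(seed)
    layers = reachable_layers(spec, n)
    sol = ValueSolution(meta={"horizon": n, "algorithm": "backward_induction"})
    u_next: dict[State, float] | None = None
    for t in range(n, 0, -1):
        u_here: dict[State, float] = {}
        for s in layers[t]:
            if t == n and spec.terminal_actions is not None:
                acts = list(spec.terminal_actions(s))
            else:
                acts = list(self_actions(spec, s))
            decomp = q_decompose(spec, u_next if t < n else None, t, s, acts)
            qvals = {}
            for a, (iev, fev, q) in decomp.items():
                sol.iev[(t, s, a)] = iev
                sol.fev[(t, s, a)] = fev
                sol.Q[(t, s, a)] = q
                qvals[a] = q
            best_a = _pick(acts, qvals, tie_rule, rng)
            sol.policy[(t, s)] = best_a
            u_here[s] = qvals[best_a]
            sol.u[(t, s)] = qvals[best_a]
        u_next = u_here
    sol.meta["n_states"] = sum(len(l) for l in layers[1:])
    return sol


# ---------------------------------------------------------------------------
# value iteration


class _Compiled:
    """Flat-array image of a TaskSpec for vectorized Bellman backups."""

    def __init__(self, spec: TaskSpec):
        if spec.states is None:
            raise SpecError("value iteration requires an explicit state list")
        self.states = list(spec.states)
        index = {s: i for i, s in enumerate(self.states)}
        if len(index) != len(self.states):
            raise SpecError("duplicate states in state list")
        sa_off = [0]          # per-state offsets into the (s, a) rows
        row_iev: list[float] = []
        row_actions: list[Action] = []
        tr_off = [0]          # per-row offsets into the transition arrays
        tr_succ: list[int] = []
        tr_prob: list[float] = []
        for s in self.states:
            for a in self_actions(spec, s):
                row_iev.append(spec.reward(s, a) + spec.cost(s, a))
                row_actions.append(a)
                for j, p in spec.checked_transitions(s, a):
                    try:
                        tr_succ.append(index[j])
                    except KeyError:
                        raise SpecError(
                            f"successor {j!r} of state {s!r} under action {a!r} is not in the state list"
                        ) from None
                    tr_prob.append(p)
                tr_off.append(len(tr_succ))
            sa_off.append(len(row_iev))
        self.sa_off = np.asarray(sa_off, dtype=np.int64)
        self.row_iev = np.asarray(row_iev, dtype=float)
        self.row_actions = row_actions
        self.tr_off = np.asarray(tr_off, dtype=np.int64)
        self.tr_succ = np.asarray(tr_succ, dtype=np.int64)
        self.tr_prob = np.asarray(tr_prob, dtype=float)

    def backup(self, v: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray]:
        """One Bellman backup; returns (new state values, per-row Q)."""
        contrib = self.tr_prob * v[self.tr_succ]
        fev = np.zeros(len(self.row_iev))
        if len(contrib):
            sums = np.add.reduceat(contrib, self.tr_off[:-1]) if len(self.tr_off) > 1 else np.array([])
            # rows with no transitions: reduceat would grab the next row's slice
            lens = np.diff(self.tr_off)
            fev = np.where(lens > 0, sums, 0.0)
        q = self.row_iev + gamma * fev
        v_new = np.maximum.reduceat(q, self.sa_off[:-1])
        return v_new, q


def value_iteration(
    spec: TaskSpec,
    tol: float = 1e-6,
    criterion: str = "max-norm",
    max_iter: int = 100_000,
    damping: float | None = None,
    v0: np.ndarray | None = None,
    tie_rule: str = "first",
    seed: int | None = None,
    record_history: bool = False,
) -> ValueSolution:
    """Solve an infinite-horizon task by value iteration.

    ``criterion='max-norm'`` (gamma < 1) stops when ``max|dv| < tol`` and
    returns the discounted fixed point.  ``criterion='span'`` (required
    when gamma = 1) stops when ``span(dv) = max(dv) - min(dv) < tol`` and
    returns *differential* values (the average reward per stage, reported
    in ``meta['gain']``, is subtracted out).  With gamma = 1 a damped
    operator v <- (1-tau) v + tau T(v) (default tau = 0.5) is used so that
    deterministic cycles in the transition structure cannot stall the
    span; the damping leaves differential values and the rescaled gain
    unchanged.
    """
    if spec.discount == 1.0 and criterion != "span":
        raise SpecError("gamma = 1 requires the span stopping criterion (average-reward solving)")
    if criterion not in ("max-norm", "span"):
        raise SpecError(f"unknown stopping criterion {criterion!r}")
    comp = _Compiled(spec)
    nstates = len(comp.states)
    gamma = spec.discount
    tau = 1.0
    if damping is not None:
        tau = float(damping)
    elif gamma == 1.0:
        tau = 0.5
    v = np.zeros(nstates) if v0 is None else np.asarray(v0, dtype=float).copy()
    history: list[np.ndarray] = []
    last_measure = np.inf
    gain = 0.0
    for it in range(1, max_iter + 1):
        tv, _q = comp.backup(v, gamma)
        v_new = v + tau * (tv - v) if tau != 1.0 else tv
        dv = v_new - v
        if criterion == "max-norm":
            last_measure = float(np.max(np.abs(dv)))
        else:
            last_measure = float(np.max(dv) - np.min(dv))
            gain = float((np.max(dv) + np.min(dv)) / 2.0) / tau
        if record_history:
            history.append(v_new.copy())
        v = v_new
        if last_measure < tol:
            break
    else:
        raise ConvergenceError(
            f"value iteration did not converge in {max_iter} iterations "
            f"({criterion} of last change = {last_measure:.3e})"
        )
    if criterion == "span":
        v = v - v[0]  # differential values, anchored at the first state

    sol = ValueSolution(
        meta={
            "iterations": it,
            "criterion": criterion,
            "final_change": last_measure,
            "tol": tol,
            "algorithm": "value_iteration",
            "damping": tau,
        }
    )
    if criterion == "span":
        sol.meta["gain"] = gain
    if record_history:
        sol.meta["history"] = history
    # final decomposition from the converged values (undiscounted case:
    # relative action values r + C + sum p * h(j); the per-stage gain is a
    # state-independent offset and cancels in action-value differences)
    _tv, q = comp.backup(v, gamma)
    rng = np.random.default_rng(seed)
    for i, s in enumerate(comp.states):
        r0, r1 = comp.sa_off[i], comp.sa_off[i + 1]
        acts = comp.row_actions[r0:r1]
        qvals = {}
        for k in range(r0, r1):
            a = comp.row_actions[k]
            iev = comp.row_iev[k]
            sol.iev[(0, s, a)] = float(iev)
            sol.fev[(0, s, a)] = float(q[k] - iev)
            sol.Q[(0, s, a)] = float(q[k])
            qvals[a] = float(q[k])
        best_a = _pick(acts, qvals, tie_rule, rng)
        sol.policy[(0, s)] = best_a
        sol.u[(0, s)] = float(v[i])
    return sol
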