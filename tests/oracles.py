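"""Independent reference implementations used to validate the solvers.

Everything here is deliberately written without reusing the package's
dynamic-programming code paths: plain recursion, direct summation,
textbook formulas, Monte Carlo.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def expectimax_utility(spec, state, t: int) -> float:
    """Finite-horizon utility by exhaustive recursion over the outcome tree.

    Direct transcription of the definition: at the final trial the best
    immediate value; earlier, reward + cost + discounted expectation of
    the recursively enumerated continuation.  Exponential in the
    horizon — small fixtures only.
    """
    n = spec.horizon
    if t == n and spec.terminal_actions is not None:
        acts = spec.terminal_actions(state)
    else:
        acts = spec.actions(state)
    best = -np.inf
    for a in acts:
        val = spec.reward(state, a) + spec.cost(state, a)
        if t < n:
            for j, p in spec.transitions(state, a):
                if p:
                    val += spec.discount * p * expectimax_utility(spec, j, t + 1)
        best = max(best, val)
    return best


def reference_kalman(mean: float, var: float, y: float, var_obs: float) -> tuple[float, float]:
    """Scalar Bayes update by precision addition (conjugate Gaussian product)."""
    prec = 1.0 / var + 1.0 / var_obs
    post_var = 1.0 / prec
    post_mean = post_var * (mean / var + y / var_obs)
    return post_mean, post_var


def bspline_cox_de_boor(x: float, t: np.ndarray, j: int, k: int) -> float:
    """B_{j,k}(x) by the Cox-de Boor recursion on knot vector ``t``."""
    if k == 0:
        # half-open support, closed at the final knot
        if t[j] <= x < t[j + 1] or (x == t[-1] and t[j] < t[j + 1] == t[-1]):
            return 1.0
        return 0.0
    out = 0.0
    d1 = t[j + k] - t[j]
    if d1 > 0:
        out += (x - t[j]) / d1 * bspline_cox_de_boor(x, t, j, k - 1)
    d2 = t[j + k + 1] - t[j + 1]
    if d2 > 0:
        out += (t[j + k + 1] - x) / d2 * bspline_cox_de_boor(x, t, j + 1, k - 1)
    return out


def mc_pair_value(g1: float, g2: float, p_range, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo E[max(g1 p1, g2 p2)] and its standard error."""
    rng = np.random.default_rng(seed)
    a, b = p_range
    p1 = rng.uniform(a, b, n)
    p2 = rng.uniform(a, b, n)
    m = np.maximum(g1 * p1, g2 * p2)
    return float(m.mean()), float(m.std(ddof=1) / np.sqrt(n))


def beads_posterior_bayes(n_d: int, n_b: int, q: float) -> float:
    """P(blue urn | n_b of n_d blue) from binomial likelihoods, equal priors.

    Exact rational arithmetic so the identity check is not a float
    tautology.
    """
    qf = Fraction(q).limit_denominator(10**6)
    like_blue = qf**n_b * (1 - qf) ** (n_d - n_b)
    like_orange = (1 - qf) ** n_b * qf ** (n_d - n_b)
    return float(like_blue / (like_blue + like_orange))


def random_taskspec(seed: int, n_states: int = 3, n_actions: int = 2, horizon: int = 4):
    """Seeded random dense finite-horizon MDP over integer states."""
    from choicemdp.core import TaskSpec

    rng = np.random.default_rng(seed)
    states = list(range(n_states))
    rewards = rng.uniform(-1.0, 2.0, size=(n_states, n_actions))
    probs = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    return TaskSpec(
        actions=lambda s: tuple(range(n_actions)),
        reward=lambda s, a: float(rewards[s, a]),
        transitions=lambda s, a: [(j, float(probs[s, a, j])) for j in states],
        discount=float(rng.uniform(0.5, 1.0)),
        horizon=horizon,
        start=states,
        states=states,
    )


class JointBanditOracle:
    """Exact (truncated) value iteration on the *joint* two-armed lattice.

    Independent of both the package's value-iteration engine and its
    Gittins machinery: index arithmetic on a flat array, plain numpy.
    Arms whose count hits the cap are treated as known with mean R/C
    (their state freezes).  Used to verify that ranking single-arm
    restart indices reproduces the jointly optimal discounted policy.
    """

    def __init__(self, gamma: float, c_cap: int = 40, tol: float = 1e-10, alpha: float = 1.0, beta: float = 1.0):
        self.gamma = gamma
        self.c_cap = c_cap
        # per-arm state enumeration: (r, c), c <= cap, index = c(c+1)/2 + r
        arm_states = [(r, c) for c in range(c_cap + 1) for r in range(c + 1)]
        self.n_arm = len(arm_states)
        r = np.array([s[0] for s in arm_states])
        c = np.array([s[1] for s in arm_states])
        q = (r + alpha) / (c + alpha + beta)
        capped = c >= c_cap
        idx_up = np.where(capped, np.arange(self.n_arm), (c + 1) * (c + 2) // 2 + r + 1)
        idx_dn = np.where(capped, np.arange(self.n_arm), (c + 1) * (c + 2) // 2 + r)
        n = self.n_arm
        i1 = np.repeat(np.arange(n), n)
        i2 = np.tile(np.arange(n), n)
        self.q1 = q[i1]
        self.q2 = q[i2]
        # joint successor indices: arm1 sampled -> (i1', i2); arm2 -> (i1, i2')
        self.s1_up = idx_up[i1] * n + i2
        self.s1_dn = idx_dn[i1] * n + i2
        self.s2_up = i1 * n + idx_up[i2]
        self.s2_dn = i1 * n + idx_dn[i2]
        v = np.zeros(n * n)
        g = gamma
        for _ in range(100_000):
            q1v = self.q1 * (1.0 + g * v[self.s1_up]) + (1.0 - self.q1) * g * v[self.s1_dn]
            q2v = self.q2 * (1.0 + g * v[self.s2_up]) + (1.0 - self.q2) * g * v[self.s2_dn]
            v_new = np.maximum(q1v, q2v)
            delta = float(np.max(np.abs(v_new - v)))
            v = v_new
            if delta < tol:
                break
        else:
            raise RuntimeError("joint bandit oracle did not converge")
        self.Q1, self.Q2 = q1v, q2v

    def choice(self, r1: int, c1: int, r2: int, c2: int) -> int:
        """Greedy arm (1-based, arm 1 on exact ties) at joint counts."""
        i = (c1 * (c1 + 1) // 2 + r1) * self.n_arm + (c2 * (c2 + 1) // 2 + r2)
        return 1 if self.Q1[i] >= self.Q2[i] else 2

    def q_gap(self, r1: int, c1: int, r2: int, c2: int) -> float:
        i = (c1 * (c1 + 1) // 2 + r1) * self.n_arm + (c2 * (c2 + 1) // 2 + r2)
        return float(self.Q1[i] - self.Q2[i])
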