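"""Restless Gaussian two-armed bandit: Kalman beliefs + basis-approximated values.

Each arm's mean payout follows a mean-reverting random walk
``x(t) = lambda x(t-1) + (1 - lambda) theta + eta_x`` and pays
``y = x + eta_y``.  The belief state is the per-arm posterior mean and
standard deviation (Kalman sufficient statistics): sampling an arm
shrinks its variance through the Kalman gain, not sampling it lets the
variance relax toward the random-walk stationary value — so unsampled
arms drift back toward "novel" and accrue an exploration bonus.  The
infinite-horizon discounted utility over the 4-D belief space is fitted
by approximate value iteration on a B-spline (means) x truncated-power
(SDs) basis with pairwise interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .basis import ApproxValueFunction, BasisSpec, DimensionBasis, approximate_value_iteration
from .core import SpecError, TaskSpec

__all__ = [
    "GenerativeParams",
    "ArmBelief",
    "GaussianBeliefState",
    "kalman_update_chosen",
    "decay_update_unchosen",
    "outcome_grid",
    "belief_utility",
    "default_basis",
    "solve_nonstationary",
    "simulate_agent",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Constants of the decaying-random-walk payout process."""

    lam: float = 0.9836          # decay toward the attractor
    theta: float = 50.0          # attractor mean (payouts on a ~0-100 scale)
    var_x: float = 7.84          # process noise variance
    var_y: float = 16.0          # observation noise variance

    def __post_init__(self):
        if not (0.0 < self.lam <= 1.0):
            raise SpecError(f"decay must lie in (0, 1], got {self.lam}")
        if self.var_x <= 0 or self.var_y <= 0:
            raise SpecError("noise variances must be positive")

    @property
    def stationary_var(self) -> float:
        """Fixed point of the unobserved-arm variance recursion var_x/(1-lam^2)."""
        if self.lam == 1.0:
            return float("inf")
        return self.var_x / (1.0 - self.lam**2)


@dataclass(frozen=True)
class ArmBelief:
    """Posterior mean and standard deviation for one arm."""

    mean: float
    sd: float

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd < 0:
            raise SpecError(f"invalid belief ({self.mean}, {self.sd})")

    @property
    def var(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class GaussianBeliefState:
    """Joint belief b = (mean1, sd1, mean2, sd2)."""

    arm1: ArmBelief
    arm2: ArmBelief

    def arm(self, i: int) -> ArmBelief:
        if i == 1:
            return self.arm1
        if i == 2:
            return self.arm2
        raise SpecError(f"arm index must be 1 or 2, got {i}")

    def coords(self) -> tuple[float, float, float, float]:
        return (self.arm1.mean, self.arm1.sd, self.arm2.mean, self.arm2.sd)


def kalman_update_chosen(belief: ArmBelief, y: float, params: GenerativeParams = GenerativeParams()) -> ArmBelief:
    """Kalman update after observing payout ``y`` on the chosen arm.

    gain kappa = var/(var + var_y); mean += kappa (y - mean);
    var <- (1 - kappa) var.  A zero-variance belief has zero gain and is
    unchanged by any observation.
    """
    if not np.isfinite(y):
        raise SpecError(f"payout must be finite, got {y}")
    kappa = belief.var / (belief.var + params.var_y)
    mean = belief.mean + kappa * (y - belief.mean)
    var = (1.0 - kappa) * belief.var
    return ArmBelief(mean, float(np.sqrt(var)))


def decay_update_unchosen(belief: ArmBelief, params: GenerativeParams = GenerativeParams()) -> ArmBelief:
    """Propagate an unobserved arm one step through the random walk.

    mean <- lam mean + (1 - lam) theta; var <- lam^2 var + var_x.
    Repeated application converges to the stationary variance
    var_x / (1 - lam^2).
    """
    mean = params.lam * belief.mean + (1.0 - params.lam) * params.theta
    var = params.lam**2 * belief.var + params.var_x
    return ArmBelief(mean, float(np.sqrt(var)))


def outcome_grid(belief: ArmBelief, params: GenerativeParams, n_points: int = 10, n_sd: float = 2.0):
    """Discretized predictive payout distribution y ~ N(mean, var + var_y).

    ``n_points`` equally spaced points spanning +/- ``n_sd`` predictive
    standard deviations, weighted by the normal density renormalized to
    sum to 1 (so the discrete outcome law is a proper distribution).
    """
    sd_pred = float(np.sqrt(belief.var + params.var_y))
    ys = np.linspace(belief.mean - n_sd * sd_pred, belief.mean + n_sd * sd_pred, n_points)
    w = norm.pdf(ys, loc=belief.mean, scale=sd_pred)
    w = w / w.sum()
    return ys, w


@dataclass
class NonStationaryModel:
    """Fitted value function plus everything needed to evaluate beliefs."""

    value: ApproxValueFunction
    params: GenerativeParams
    gamma: float
    n_outcomes: int = 10
    mean_range: tuple[float, float] = (0.0, 100.0)
    sd_range: tuple[float, float] = (0.5, 14.0)
    clip_count: int = field(default=0)

    def _clip(self, b: ArmBelief) -> ArmBelief:
        """Clip a belief into the basis evaluation envelope for lookup."""
        m = min(max(b.mean, self.mean_range[0]), self.mean_range[1])
        s = min(max(b.sd, self.sd_range[0]), self.sd_range[1])
        if (m, s) != (b.mean, b.sd):
            self.clip_count += 1
        return ArmBelief(m, s)

    def successors(self, state: GaussianBeliefState, arm: int) -> list[tuple[GaussianBeliefState, float]]:
        chosen = state.arm(arm)
        other = state.arm(3 - arm)
        other_next = self._clip(decay_update_unchosen(other, self.params))
        ys, w = outcome_grid(chosen, self.params, self.n_outcomes)
        out = []
        for y, p in zip(ys, w):
            chosen_next = self._clip(kalman_update_chosen(chosen, float(y), self.params))
            nxt = GaussianBeliefState(chosen_next, other_next) if arm == 1 else GaussianBeliefState(other_next, chosen_next)
            out.append((nxt, float(p)))
        return out

    def action_values(self, state: GaussianBeliefState) -> dict[int, float]:
        """Q per arm: IEV = belief mean; FEV = discounted expected v_hat."""
        q = {}
        for arm in (1, 2):
            succ = self.successors(state, arm)
            coords = np.array([s.coords() for s, _ in succ])
            probs = np.array([p for _, p in succ])
            q[arm] = state.arm(arm).mean + self.gamma * float(probs @ self.value(coords))
        return q

    def utility(self, state: GaussianBeliefState) -> float:
        return max(self.action_values(state).values())


def belief_utility(model: NonStationaryModel, state: GaussianBeliefState) -> tuple[dict[int, float], float]:
    """Per-arm action values and their max at a belief state."""
    q = model.action_values(state)
    return q, max(q.values())


def default_basis(
    mean_knots: tuple[float, ...] = (-30.0, 50.0, 130.0),
    sd_knots: tuple[float, ...] = (0.25, 1.0, 3.0, 5.0, 15.0),
    mean_grid: tuple[float, ...] = (0.0, 12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 87.5, 100.0),
    sd_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 14.0),
) -> BasisSpec:
    """Default belief-space basis: cubic B-splines over the means,
    quadratic truncated-power polynomials over the SDs, pairwise
    interactions, dimensions ordered (mean1, sd1, mean2, sd2)."""
    mean_dim = DimensionBasis("bspline", order=3, knots=mean_knots)
    sd_dim = DimensionBasis("piecewise", order=2, knots=sd_knots)
    return BasisSpec(
        dimensions=[mean_dim, sd_dim, mean_dim, sd_dim],
        interaction_order=2,
        evaluation_grid=[mean_grid, sd_grid, mean_grid, sd_grid],
    )


def solve_nonstationary(
    gamma: float = 0.9,
    params: GenerativeParams = GenerativeParams(),
    basis: BasisSpec | None = None,
    tol: float = 1e-3,
    n_outcomes: int = 10,
    max_iter: int = 100_000,
) -> NonStationaryModel:
    """Fit the belief-space value function by approximate value iteration."""
    if basis is None:
        basis = default_basis()
    model = NonStationaryModel(
        value=None,  # filled below
        params=params,
        gamma=gamma,
        n_outcomes=n_outcomes,
        mean_range=(min(basis.evaluation_grid[0]), max(basis.evaluation_grid[0])),
        sd_range=(min(basis.evaluation_grid[1]), max(basis.evaluation_grid[1])),
    )
    grid_states = [
        GaussianBeliefState(ArmBelief(m1, s1), ArmBelief(m2, s2))
        for (m1, s1, m2, s2) in basis.grid_points()
    ]

    def actions(s):
        return (1, 2)

    def reward(s, a):
        return s.arm(a).mean

    def transitions(s, a):
        return [(succ.coords(), p) for succ, p in model.successors(s, a)]

    spec = TaskSpec(
        actions=actions,
        reward=reward,
        transitions=transitions,
        discount=gamma,
        states=grid_states,
        name="nonstationary-bandit",
    )
    # the approximate solver consumes coordinate tuples as states
    spec_coords = replace(
        spec,
        states=[s.coords() for s in grid_states],
        actions=lambda s: (1, 2),
        reward=lambda s, a: s[0] if a == 1 else s[2],
        transitions=lambda s, a: transitions(
            GaussianBeliefState(ArmBelief(s[0], s[1]), ArmBelief(s[2], s[3])), a
        ),
    )
    vf = approximate_value_iteration(spec_coords, basis, tol=tol, max_iter=max_iter)
    vf.meta["belief_clips_during_fit"] = model.clip_count
    model.value = vf
    return model


def simulate_agent(
    model: NonStationaryModel,
    trials: int,
    seed: int,
    mean_mode: str = "generative",
    clamp: tuple[float, float] = (45.0, 55.0),
) -> dict[str, np.ndarray]:
    """Simulate the greedy agent against the (or a clamped) payout process.

    ``mean_mode='generative'`` draws the true means from the random walk;
    ``'clamped'`` locks them at ``clamp`` while the agent still assumes
    non-stationarity.  Beliefs start at the attractor mean with a large
    prior SD so both arms are initially worth exploring.  Same seed, same
    trajectory.
    """
    if mean_mode not in ("generative", "clamped"):
        raise SpecError(f"unknown mean mode {mean_mode!r}")
    rng = np.random.default_rng(seed)
    p = model.params
    prior_sd = float(np.sqrt(1000.0))
    b1 = ArmBelief(p.theta, prior_sd)
    b2 = ArmBelief(p.theta, prior_sd)
    x = np.array(clamp, dtype=float) if mean_mode == "clamped" else np.array([p.theta, p.theta])
    out = {k: np.zeros(trials) for k in ("x1", "x2", "payout", "choice", "mu1", "sd1", "mu2", "sd2", "Q1", "Q2")}
    for t in range(trials):
        state = GaussianBeliefState(model._clip(b1), model._clip(b2))
        q = model.action_values(state)
        choice = 1 if q[1] >= q[2] else 2
        y = float(x[choice - 1] + rng.normal(0.0, np.sqrt(p.var_y)))
        out["x1"][t], out["x2"][t] = x
        out["choice"][t] = choice
        out["payout"][t] = y
        out["mu1"][t], out["sd1"][t] = b1.mean, b1.sd
        out["mu2"][t], out["sd2"][t] = b2.mean, b2.sd
        out["Q1"][t], out["Q2"][t] = q[1], q[2]
        if choice == 1:
            b1 = kalman_update_chosen(b1, y, p)
            b2 = decay_update_unchosen(b2, p)
        else:
            b2 = kalman_update_chosen(b2, y, p)
            b1 = decay_update_unchosen(b1, p)
        if mean_mode == "generative":
            x = p.lam * x + (1.0 - p.lam) * p.theta + rng.normal(0.0, np.sqrt(p.var_x), size=2)
    return out
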