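# Methods

`choicemdp` implements normative dynamic-programming accounts of six
value-based choice tasks. Every task is cast as a Markov decision
process (MDP) — or, where the relevant state is a belief over hidden
quantities, a partially observable MDP solved on its information
state — and the action value is always decomposed as

    Q(s, a) = IEV(s, a) + FEV(s, a)
    IEV = r(s, a) + C(s, a)
    FEV = gamma * sum_j p(j | s, a) * u(j)

where `r` is the expected immediate reward, `C` a (usually nonpositive)
cost-to-sample, and `u` the utility of the successor state. Exploration,
information sampling and patch leaving are all choices of a larger FEV
over a larger IEV; the decomposition is stored explicitly in every
solution object so that trade-off can be inspected per trial and state.

## Exact solvers (`core`)

Finite-horizon tasks are solved by backward induction over lazily
enumerated reachable state layers. Trials are 1-based and t = N is the
final *decision* trial: an action is still taken there, and its value
has no future component because no further choice follows. (This is the
reading under which a 1-state chain with unit reward and N = 3 has
u_1 = 3, and under which the forced guess at the beads horizon and the
forced accept at the sampling horizon come out right.)

Infinite-horizon tasks use value iteration on a compiled flat-array
image of the task (per-row transition index/probability arrays,
`np.add.reduceat` backups), with two stopping rules:

* **max-norm** (gamma < 1): stop when `max|dv| < tol`; default tol 1e-6,
  iteration cap 100,000.
* **span** (required at gamma = 1): stop when `span(dv) < tol`; the
  returned values are differential (bias) values anchored at the first
  state, and the gain — the average reward per stage, estimated as the
  midpoint of the change vector — is reported separately. Because a
  fixed policy in the patch task traverses deterministic delay chains,
  its chain is periodic and the raw span need not settle; gamma = 1
  solving therefore applies the standard aperiodicity transformation
  v <- (1 - tau) v + tau T(v) with tau = 0.5, which leaves the
  differential values unchanged and scales the per-iteration gain by
  tau (undone on report).

Ties in the greedy policy break to the lowest-index action; simulators
can opt into seeded-random tie-breaking. Transition distributions are
validated (nonnegative, sum to 1 within 1e-9) on every compile/visit.

## Basis approximation (`basis`)

Tasks whose information space is continuous (restless bandit) or too
large (novelty bandit) are solved approximately: utilities are written
as v(s) = sum_i a_i phi_i(s), coefficients are fitted by least squares
on an evaluation grid, and Bellman backups alternate with projection
until the fitted grid values change by less than `tol` in max norm.
Per-dimension families are truncated-power piecewise polynomials
(global x^0..x^K plus (x - t_j)_+^K per knot), clamped B-splines of
degree K (via `scipy.interpolate.BSpline`), and indicator columns for
exact tabular checks. Multi-dimensional bases take one intercept, each
dimension's block with its constant-equivalent column removed, and —
at `interaction_order = 2` — pairwise products of main-effect columns
across distinct dimensions. Full tensor products are not built: they
are what makes the projection intractable and the iteration divergent,
and quadratic interactions were where the fits stopped improving on
these tasks.

Numerical choices:

* Condition-number threshold 1e10 for declaring the design matrix
  rank-deficient (error names the implicated columns).
* `drop_degenerate` (default on) removes columns that are identically
  zero or exactly collinear on the evaluation grid, keeping the
  earliest independent set — e.g. a truncated-power term whose knot
  lies outside the grid range. Off-grid evaluation reuses the fitted
  column set by label, and task modules clip lookups to the grid
  envelope, so the dropped terms can never be silently resurrected.
* Extrapolation beyond the outer B-spline breakpoints continues the
  end polynomial pieces; belief lookups are clipped to the evaluation
  envelope and a counter logs clips.
* Divergence (fitted values beyond 1e12) raises with the trace of
  recent changes — the classic over-rich-basis failure.
* Convergence diagnostics stored per fit: residual variance of the
  projection and the slope of v-hat_{n+1} against v-hat_n (should be
  ~1 after convergence).

## Stationary two-armed bandit (`stationary`)

Beta-Bernoulli arms with Beta(alpha, beta) priors; the information
state per arm is the (rewards, choices) count pair, posterior
pseudo-counts R = r + alpha, C = c + alpha + beta, posterior mean R/C.
The joint task is undiscounted and finite-horizon, solved exactly.
Sampling an arm moves it to (r+1, c+1) with probability R/C, else to
(r, c+1); the posterior mean is a martingale under this law, so all
horizon effects come through the max operator, not through drift.
Rewards are unit magnitude per success (configurable scalar).

The generic layered solver is mirrored by a vectorized implementation
(`_LayeredValues`, index arithmetic on contiguous count layers) used by
the horizon-sweep and scenario-replay analytics; the two are checked
equal in the tests. Exact solving is refused beyond horizon 120 (the
joint lattice grows as the fourth power of the horizon).

The exploration bonus at a joint state is FEV(less-sampled arm) minus
FEV(more-sampled arm) at the first trial of the remaining horizon. The
probe-then-commit heuristic (`heuristic_two_phase_value`) reproduces
the closed-form two-branch average that rationalizes the bonus.

## Gittins indices (`gittins`)

For discounted stationary bandits the jointly optimal policy ranks
per-arm indices. The index of an arm state is computed by the
restart-in-state formulation: on the arm's own count lattice every
state offers *continue* or *restart to the queried state*, and the
index is the fixed-point value of the queried state under value
iteration. The lattice is rooted at the queried counts and truncated
at a configurable depth (default 200 further samples); capped states
are absorbing at the known-arm value (R/C)/(1 - gamma). Indices are
cached by (R, C, gamma, depth) — they never depend on the other arm.
Indices require gamma < 1 and are reported on the discounted
total-value scale (a certainly-rewarding unit arm approaches
1/(1 - gamma)); they are not value estimates of the joint problem.
The test suite verifies the index ranking against an independent
truncated joint-lattice solver on all 784 joint states with both
choice counts at most 6 (gamma 0.9): zero disagreements.

## Restless Gaussian bandit (`nonstationary`)

Generative model per arm: mean x(t) = lam x(t-1) + (1-lam) theta + eta_x,
payout y = x + eta_y, with defaults lam = 0.9836, theta = 50,
var_x = 7.84, var_y = 16 (payouts on a ~0-100 point scale). The belief
state is the per-arm Kalman mean and SD. The chosen arm updates with
gain kappa = var/(var + var_y); the unchosen arm decays toward theta
and its variance relaxes toward var_x/(1 - lam^2) ~ 241 — an unsampled
arm literally drifts back toward novelty.

The outcome integral in the backup uses the predictive law
y ~ N(mean, var + var_y), discretized as 10 equally spaced points over
±2 predictive SDs weighted by the renormalized normal density (the
point count and range are task constants; the weighting is our choice,
made so the discrete law is a proper distribution — a 1000-point
quadrature moves action values by <0.2%). The 4-D value function
(mean1, sd1, mean2, sd2) uses cubic B-splines over the means
(breakpoints -30, 50, 130; evaluated at 0:12.5:100) and quadratic
truncated-power polynomials over the SDs (knots 0.25, 1, 3, 5, 15;
evaluated at 0.5, 1, 2, 3, 4, 5, 7, 14), with pairwise interactions.
The 0.25 and 15 knots fall outside the SD evaluation range and their
columns are dropped as degenerate (see above); lookups clip to the
envelope, so this is exactly the fitted family.

Agent simulation starts beliefs at mean theta with prior variance 1000
(large, so both arms are initially worth exploring; configurable — the
task constants do not pin it down) and supports a clamped mode that
locks the true means (e.g. 45/55) while the agent still assumes
non-stationarity. Same seed, same trajectory.

## Novelty bandit (`novelty`)

Three Beta(1,1)-Bernoulli arms; each trial, with probability
p_switch = 0.05, a uniformly chosen arm (possibly the one just
sampled) is replaced by a novel option, resetting it to the prior root
(R, C) = (1, 2). Sampling arm i yields 7 distinct successors —
{reward, no reward} x {no switch, switch of each other arm}, plus a
single merged branch for replacement of the chosen arm (the reset
wipes the outcome) — and the union over the three actions is 21
states. The task is infinite-horizon and discounted; values are fitted
on per-arm (N = C, p = R/C) coordinates with cubic B-splines
(N breakpoints 0 and 150, p breakpoints 0 and 1) and pairwise
interactions, on the grid N = exp(0 : 5/4 : 5) (a geometric ladder
from 1 to ~148; N values need not be integers), p = 0 : 0.25 : 1.

The novelty bonus at a state is Q(reset arm) - Q(comparison arm). It
rises with the discount (longer horizon to exploit what is learned)
and falls with p_switch (substitution truncates that horizon);
-1/ln(gamma) converts a discount into the trial count at which
weighting reaches 1/e. A caveat found while validating: at gamma near
1 the bonus is a small difference of large values and the default
5-point N ladder's residual error is the same order as the signal —
the discount-sweep tests therefore fit on a 7-point N ladder (same
knots, same p grid), under which the bonus is strictly increasing
through gamma = 0.99. Grid density here is an accuracy knob of the
approximation, assessed by residual variance, not a property of the
task.

## Beads / urn information sampling (`beads`)

Majority-urn fraction q = 0.6, at most 12 draws, correct guess worth
1, error worth 0, cost per draw -0.005. State (n_d, n_b); with equal
urn priors the blue-urn posterior is the logistic closed form
p_b = 1/(1 + (q/(1-q))^(n_d - 2 n_b)), verified exactly against the
binomial Bayes computation in rational arithmetic. Guesses terminate
(zero FEV); drawing transitions up/down the lattice under the
posterior-predictive bead law. Backward induction runs from the forced
guess at n_d = 12 down to the empty state. The stop rule reported for
a bead sequence is the first draw after which the best guess strictly
exceeds the draw value (with a 1e-12 float guard, so the exact ties
that arise at zero sampling cost count as drawing on). One stopping
subtlety worth documenting: with any negative cost the observer stops
on an alternating B/O/B/O sequence at draw 11 — after an odd draw the
net evidence is one bead, and with a single draw remaining the
expected best guess after one more bead equals the current best guess
exactly (martingale, no sign crossing), so the last draw buys nothing.

## Patch foraging (`patch`)

Explicit-time MDP on 100 ms steps, juice in 20 uL units. Choice states
(juice, delay) offer stay — a 4-step reward chain delivering the
current juice at its last state, then depletion by one unit — or
leave — a travel chain of the *currently known* delay, then a fresh
patch whose delay is resampled uniformly from the 11 values 500..10500
ms. Both chains end in a 15-step ITI returning to a choice state; the
delay resample is the model's only stochastic transition. Fresh-patch
juice defaults to 10 units (the task constants do not print it; the
cap is configurable).

Discounted (default gamma = 0.9998 per 100 ms, a ~8 minute time
constant; all qualitative claims are checked across a gamma sweep),
the stay-minus-leave difference rises with the delay ahead, so longer
travel means leaving at lower juice — the marginal-value-theorem
pattern. Undiscounted, the current delay is paid exactly once
whichever action is taken now, so it cancels in the differential
stay-minus-leave values: the solved surfaces agree across all 11
delays to ~1e-9, and residence time is constant. Residence times are
read off the policy's juice frontier and cross-checked by forward
simulation.

## Foraging by sampling (`sampling`)

Six known gamble magnitudes per bout (defaults 20, 40, 60, 80, 100,
130 points, drawn from the task's 20..130-by-10 pool), 15 unordered
pairs, horizon 60, cost per resample -7. A pair's value is
E[max(g1 p1, g2 p2)] with p1, p2 independent uniform on [0.2, 0.9] —
the probabilities sit under the max because the decision stage takes
the better revealed product. The double integral is normalized by
(b - a)^2 so the value is on the points scale, and evaluated by
200x200 midpoint quadrature (the integrand is bilinear away from the
max kink; the grid gives ~1e-6 relative accuracy, validated against
Monte Carlo). Backward induction with a forced accept at the horizon;
away from the horizon the resample value is offer-independent, so the
policy is a constant-threshold rule: accept exactly when the offered
pair beats the fixed value of sampling on.

## Configuration and outputs (`io`, `cli`)

YAML configs validate against per-task schemas (unknown keys rejected
by name, omitted parameters filled from defaults with provenance
recorded); solutions export as tidy (t, state, action, IEV, FEV, Q,
chosen) tables in CSV (12 significant digits) or JSON; runs write a
resolved-config copy and an ISO-timestamped log line with seed,
library versions and iteration counts. The `choicemdp` console script
exposes one subcommand per task.

## What the tests do and do not show

All solver-level checks are against independent oracles: exhaustive
recursion for finite horizons, rational-arithmetic Bayes for the urn
posterior, Monte Carlo for the pair value, a precision-form Bayes
filter for the Kalman update, a Cox-de Boor recursion for the
B-splines, and a flat-array joint-lattice solver for the Gittins
ranking. Qualitative claims (bonus monotonicities, sampling-rate
orderings, delay (in)sensitivity) are asserted at the task constants
above, at problem sizes chosen to keep the full suite to minutes:
bandit horizons to 50, 20 seeds x 500 trials for the clamped restless
simulations, the evaluation grids listed per task. Nothing here
touches empirical choice data; agreement of a human or animal with
these policies is a separate scientific question the package does not
address, and the approximate solvers inherit the usual caveat that a
fitted basis is only as good as its residual diagnostics on the region
actually visited.

## Known limitations

* Exact bandit solving is bounded by the O(N^4) joint lattice; longer
  horizons need the index or approximate machinery.
* The basis family is fixed (no adaptive knots, no regularized
  projection); raising the polynomial order beyond cubic is known to
  destabilize the iteration and is not exposed as a default.
* Gittins indices are truncation approximations (depth-capped
  lattice); at gamma = 0.9 the induced policy error is below the
  tie-detection level but very high discounts would need deeper caps.
* The novelty-bonus signal at gamma >= 0.99 sits near the resolution
  of the default evaluation grid (see above).
* The undiscounted patch solution reports differential values only;
  gains of transient actions are not separately ranked (no sensitive
  discount optimality).
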