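# choicemdp

Normative Markov-decision-process models of the laboratory choice tasks
used to study the explore–exploit trade-off, information sampling and
foraging — written for computational-neuroscience and decision-science
researchers who want the *optimal* policy and its value decomposition
for these tasks, rather than a heuristic fit.

Six tasks are implemented end to end:

| task | model | solver |
| --- | --- | --- |
| stationary two-armed bandit | Beta-Bernoulli POMDP, finite horizon, undiscounted | exact backward induction |
| restless (Gaussian) two-armed bandit | Kalman belief POMDP, infinite horizon, discounted | B-spline approximate value iteration |
| 3-armed novelty bandit (stochastic option substitution) | Beta-Bernoulli POMDP, infinite horizon, discounted | B-spline approximate value iteration |
| beads / urn information sampling | finite-horizon POMDP with cost-to-sample | exact backward induction |
| patch leaving | explicit-time MDP, discounted and average-reward | value iteration (max-norm / span) |
| foraging by sampling | gamble-pair MDP, finite horizon | exact backward induction |

plus Gittins (dynamic allocation) indices for Beta-Bernoulli arms via
the restart-in-state fixed point.

The common core is the decomposition of every action value into an
immediate and a future expected value,

```
Q(s,a) = IEV(s,a) + FEV(s,a)
IEV    = r(s,a) + C(s,a)                      # reward + cost-to-sample
FEV    = gamma * sum_j p(j|s,a) * u_{t+1}(j)  # discounted continuation
```

Exploration (bandits), drawing another bead (sampling) and leaving a
patch (foraging) are all choices whose value is carried by the FEV;
every solution object exposes the split per trial, state and action.
See `docs/methods.md` for the models, parameters and numerical choices.

## Worked example: the exploration bonus

An agent has sampled option 1 six times and been rewarded three times;
option 2 has never been sampled. Both arms then have posterior mean
0.5 — identical immediate value — yet with 50 trials remaining the
optimal policy prefers the unsampled arm:

```python
>>> from choicemdp import BetaArmState, BanditJointState, exploration_bonus
>>> s = BanditJointState(BetaArmState(r=3, c=6), BetaArmState(r=0, c=0))
>>> exploration_bonus(s, horizon=50)
0.08929204136529734
```

The bonus is the FEV gap: sampling the unknown arm is worth ~0.089
extra expected rewards over the horizon, purely because finding it
better than 0.5 lets the agent exploit it for the remaining trials,
while finding it worse costs little (switch back). Replaying the
fixed scenario behind that state shows the preference flip as it
happens — option 1 is rewarded three times and then misses once, and
at trial 5 the action values cross:



```python
>>> from choicemdp import scenario_eval
>>> recs = scenario_eval("1+ 1+ 1+ 1-", horizon=50)
>>> r = recs[4]                      # trial 5, state 3/4 : 0/0
>>> round(r["Q1"], 4), round(r["Q2"], 4)
(32.741, 32.7597)
>>> round(r["iev1"], 4), round(r["iev2"], 4)
(0.6667, 0.5)
```

Option 1 still has the larger immediate value (posterior mean 4/6 vs
1/2), but the future term overturns it: Q(2) > Q(1). A back-of-envelope
version of the same quantity is also available:

```python
>>> from choicemdp import heuristic_two_phase_value
>>> heuristic_two_phase_value(p_known=0.7, p_hi=0.8, p_lo=0.2, n_probe=10, n_total=100)
{'stay_value': 70.0, 'branch_hi': 80.0, 'branch_lo': 65.0, 'average': 72.5, 'bonus': 2.5}
```

Probing a 50/50 alternative (80% vs 20% payer) for 10 of 100 trials
yields 72.5 expected rewards against 70 for always staying — a 2.5
reward exploration bonus.

The same machinery answers the other tasks' questions, e.g. when an
ideal observer should stop buying beads:

```python
>>> from choicemdp import optimal_stop_trial, BeadsParams
>>> optimal_stop_trial("BBOBBBOBBBBB", BeadsParams())   # q=0.6, C_s=-0.005
(6, 'blue')
```

## Command line

One subcommand per task, emitting tidy CSV value tables:

```bash
choicemdp solve-bandit --horizon 8 --prior 1,1 --out bandit.csv
choicemdp gittins --gamma 0.9 --cmax 50 --out indices.csv
choicemdp simulate-nonstationary --gamma 0.99 --trials 500 --seed 1 --clamp 45,55
choicemdp solve-beads --cost -0.025
choicemdp solve-patch --gamma 0.9998
choicemdp solve-sampling --gambles 20,40,60,80,100,130 --cost -7
choicemdp run config.yaml          # YAML-driven, writes resolved config + log
```

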