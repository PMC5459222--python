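# waitgo

Reward-rate-optimal decision boundaries and wait/go boundary inference
for Bernoulli-cue expanded-judgment tasks.

## The problem

In an expanded-judgment task a decision maker watches a stream of binary
cues — each points up with probability `u = 1/2 + ε` when the hidden
world state is *up* and `u = 1/2 − ε` when it is *down* — and at any
moment may either **wait** for another cue or **go** with the more
likely option. Blocks last a fixed time and every correct choice earns a
reward, so the rational objective is the *reward rate* ρ: expected
reward per unit time, counting the intertrial delay `D_C` after correct
and `D_I` after incorrect choices. The state of the decision maker is
the lattice point `(t, x)` (cue count, accumulated evidence), and a
*decision boundary* θ(t) is the evidence level at which accumulation
stops. Whether the optimal θ(t) is constant, decreasing or increasing
depends on the mixture of trial difficulties: with a single difficulty
it is constant; when impossible trials (ε = 0) are mixed in, time itself
becomes informative about difficulty and the optimal boundary collapses
to zero; with two moderate difficulties it can even rise.

`waitgo` is for computational cognitive scientists who want to

1. **derive** reward-rate-optimal wait/go policies by average-reward
   dynamic programming (`solve_optimal_policy`, `extract_boundary`),
2. **map** the reward-rate landscape of all linear boundaries
   (`landscape`, `evaluate_reward_rate` — exact, by forward propagation
   of the random-walk occupancy),
3. **simulate** cohorts of threshold or probabilistic agents playing
   fixed-duration blocks, with internal noise, drift variability,
   binomial information loss and nondecision lag
   (`simulate_cohort`, `simulate_trials`),
4. **infer** boundaries from trial records with the wait/go logistic
   regression `logit P(go) = β₀ + β_T·T + β_X·X`, its *line of
   indifference* `X = −(β_T/β_X)·T − β₀/β_X` (slope in degrees as a
   boundary-slope proxy), circular slope differences
   `Δm = ((m_e − m_m + 90) mod 180) − 90`, bootstrap CIs, nondecision
   estimation and the chance-accuracy exclusion screen,
5. **compare** fixed vs time-varying boundary models by BIC
   (`compare_boundary_models`).

## Worked example

```python
import numpy as np
from waitgo import (TaskConfig, solve_optimal_policy, extract_boundary,
                    landscape, run_experiment_preset)

# Mixed-difficulty task: drifts 0.22 and 0, D_I = 50 ISI units, D_C = D_I/3
task = TaskConfig.mixed((0.22, 0.0), 50/3, 50)
policy = solve_optimal_policy(task)          # average-reward DP
theta = extract_boundary(policy).theta
print(policy.gain)                            # 0.02218547...  reward per ISI unit
print(theta[:16])                             # [3 3 3 2 2 2 2 2 2 2 2 2 2 2 1 1]
print(theta.min())                            # 0.0  -> boundary collapses to zero

# Landscape of linear boundaries for the easy task: peak at a flat bound of 3
grid = landscape(TaskConfig.single(0.22, 50/3, 50))
print(grid.argmax)                            # (0.0, 3.0)  (slope deg, intercept)

# Full synthetic experiment: 24 optimal agents, easy/difficult/mixed blocks
bundle = run_experiment_preset("exp1", n_participants=24, seed=1)
s = bundle["summary"]
print(round(s["mean_slope"]["easy"], 2),      # 2.23
      round(s["mean_slope"]["mixed"], 2))     # -5.19
print(round(s["mean_delta_deg"], 2),          # 7.43  (easy minus mixed, degrees)
      round(s["t_stat"], 2))                  # 5.4
```

The inferred indifference-line slope is clearly more negative in mixed
games than in easy games — the signature of a collapsing boundary that
the optimal policy predicts when impossible trials are mixed in.

A CLI mirrors the library: `waitgo solve | landscape | simulate | infer
| compare | run` (see `waitgo --help`).

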