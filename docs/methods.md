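# Methods

## Model

A trial presents i.i.d. binary cues δX ∈ {+1, −1}, with
P(δX = +1) = u, u = ½ + ε when the hidden world state is *up* and
u = ½ − ε when it is *down*. The drift magnitude ε ∈ [0, ½] sets
difficulty. Time is measured in interstimulus-interval (ISI) units, one
per cue; all millisecond quantities are converted once at configuration
time. The decision maker's state is (t, x) — cue count and accumulated
evidence — and at each state it chooses *wait* (one more cue, one time
unit) or *go* (commit to the more likely world). Correct choices earn a
reward R and are followed by a delay D_C; errors by D_I. Trials renew at
(0, 0), making the long-run objective the average reward per unit time,
ρ.

### Beliefs

With a difficulty mixture {ε_j, w_j} and world prior p(up), the
posterior over (level j, world s) at (t, x) is proportional to
w_j·p(s)·u_{j,s}^{n⁺}(1 − u_{j,s})^{n⁻}, where n⁺ = (t + x)/2 and
n⁻ = (t − x)/2 count up/down cues. Computed in log space
(`scipy.special.xlogy` + logsumexp) so extreme drifts (ε = ½) and long
paths are exact. States unreachable under every level fall back to the
prior; they carry no occupancy so this choice never affects results.

### Optimal policy

The differential value h and gain ρ satisfy

    h(t, x) = max{ wait: −ρ + E[h(t+1, x±1)],
                   go:   R·P_c − ρ·(P_c·D_C + (1 − P_c)·D_I) + h(0,0) }

with h(0, 0) ≡ 0 and P_c = max posterior world probability. Time
accounting: a wait costs exactly one ISI unit; a go costs only the
realized intertrial delay (the next trial starts when the delay ends —
no extra unit for the response itself). The solver is policy iteration
with exact evaluation: given ρ, one backward-induction sweep over the
truncated lattice produces the greedy policy; that policy's gain is then
recomputed *exactly* by forward propagation of the random-walk occupancy
(see below) and the loop repeats until the policy is stable and
|Δρ| < tol (default 1e−10; iteration cap 200 — convergence is typically
< 10 sweeps). A suite test verifies the returned policy satisfies the
optimality equations state by state. Ties between wait and go (within
1e−9) are resolved toward go, which yields the lowest boundary
consistent with optimality and deterministic output. When forced to go
at x = 0 the direction is a fair coin.

The lattice is truncated at t_max = 100 with forced go on the horizon
row; only parity-valid states (t + x even, |x| ≤ t) are meaningful. A
test asserts action-map invariance away from the horizon when t_max is
doubled. Boundary traces extracted near the horizon taper artificially
in the last ~10 time steps; analyses of boundary shape ignore that tail.

### Boundary extraction on a parity lattice

The frontier θ(t) = min{x ≥ 0 : go(t, x)} alternates between adjacent
integers on a parity lattice (evidence 3 is only reachable at odd t).
`extract_boundary` therefore reads the frontier off the time pair
{t, t+1}, which covers both parities, scanning forward when neither time
has a reachable go state (early times where the boundary exceeds the
largest reachable evidence). This makes a constant-threshold policy
report a constant θ and an all-go policy report θ ≡ 0.

### Exact reward rate

For any policy with a finite wait region, per difficulty level the
occupancy of the ±1 walk (conditioned on world = up; all boundaries here
are symmetric, so the down world is a mirror image) is propagated
forward; go states absorb, accumulating P_c (mass at x > 0, plus half
the mass at x = 0) and E[T] (expected cue count at absorption). The rate
is the renewal-reward ratio

    ρ = R·Σ_j w_j P_c(j)  /  Σ_j w_j (E[T](j) + P_c(j)·D_C + (1 − P_c(j))·D_I),

i.e. mixture-averaged reward over mixture-averaged cycle time.

### Landscape

Linear boundaries θ(t) = max(0, intercept + tan(slope)·t), symmetric
about x = 0, with *go when |x| ≥ θ(t)* (boundary states are go — the
same convention as extraction). Slopes are degrees, arctan of the
gradient in evidence units per ISI unit. Default grid: slopes −80°…80°
in 2° steps, intercepts 0…15 in steps of 1 — on an integer evidence
lattice finer intercepts cannot change a constant-boundary policy, and
the landscape optimum (slope 0°, intercept 3 for the fast easy task) is
on this lattice. Argmax tie-break: lowest intercept, then slope nearest
zero.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes: per
trial a world state (prior ½), a difficulty drawn from the mixture, the
full presented cue sequence, the response, correctness and the decision
time in cue counts; fixed-duration blocks accumulate trials while the
clock (cues + realized intertrial delays) runs, and a trial in progress
at expiry is discarded (only completed choices are recorded).

Agent families and degradations (all independent knobs):

- **threshold** (rise-to-boundary): respond when internal evidence
  reaches θ(t); internal evidence = registered cues + accumulated
  Gaussian noise.
- **probabilistic**: at each step go with probability
  logistic(β₀ + β_T·t + β_X·|x|), the generative mirror of the
  inference model.
- `sigma_internal` — per-sample SD of additive integration noise.
  Default in the pipeline: 0.5 evidence units, a value that produces
  visible trial-to-trial variability (easy-game accuracy ≈ 0.9 at a
  boundary of 3) without washing out the evidence signal; 0 is available
  for exact tests.
- `sigma_drift = 0.35` — trial-to-trial perturbation of ε; the
  resulting u is clipped to [0.02, 0.98] to keep Bernoulli draws valid
  (the perturbation model itself gives no truncation rule).
- `p_attend = 0.7` — binomial information loss: each cue registers with
  this probability.
- `nd_samples` — integer nondecision lag: the response is recorded that
  many cues after the internal decision, and the cues shown in between
  are appended to the record without influencing the choice. Sub-sample
  lags are out of scope.

What the generator does **not** emulate: visual interference between
cues, attention fluctuations beyond binomial loss, millisecond-scale
response-time structure inside an ISI, learning or session-order
effects, and participant payment schemes. Passing recovery tests on
these cohorts therefore shows the inference machinery is sound under
the stated noise models — not that real observers satisfy them.

## Inference

1. **Nondecision lag**: reverse each cue sequence, align on the
   response, and compute p_t — the fraction of trials whose cue at
   reversed index t matches the response (trials shorter than t are
   excluded from p_t). Cues inside the nondecision window are
   uncorrelated with the response (p ≈ accuracy-weighted drift,
   ≈ 0.68 for ε = 0.2), while the boundary-crossing cue matches almost
   always; nd = first index with p_t > 0.75, minus one. The lag is
   estimated per participant from the easy games only and applied to
   all conditions. If no index exceeds the threshold within `max_lag`
   the estimate saturates with a warning flag.
2. **Stripping**: drop the last nd cues of each trial and recompute the
   decision state at t − nd; trials that do not survive are dropped and
   counted.
3. **Wait/go table**: each trial contributes wait rows at
   t = 1…decision_t − 1 with the running evidence and one go row at the
   final state; immediate guesses contribute a lone (0, 0, go) row; no
   (0, 0, wait) row is emitted since the first opportunity to act
   follows the first cue. Evidence is aligned with the trial's final
   response (X = x·sign(response)) so both symmetric boundaries map to
   one positive crossing level. In mixed games only trials of the
   matched difficulty enter a comparison with a single-difficulty game.
4. **Logistic fit**: statsmodels Logit MLE. Perfectly separable tables
   (noiseless agents) have no finite MLE; the estimator then falls back
   to a weak ridge penalty (λ = 1e−4 on β_T and β_X only) and flags the
   fit. The reported log-likelihood is always the unpenalized one.
5. **Line of indifference**: gradient −β_T/β_X, intercept −β₀/β_X,
   slope in degrees. |β_X| < 1e−8 marks a time-dominated (deadline-like)
   fit; its slope saturates just inside ±90° with the sign opposite to
   β_T.
6. **Circular slope difference** Δm = ((m_e − m_m + 90) mod 180) − 90,
   in degrees (the +90/mod-180 structure presumes degrees): steep
   increasing and steep decreasing boundaries are close. Note the
   estimator is a *systematically related proxy* of the generating
   boundary slope, not an unbiased estimator of it — recovery tests
   assert ordering and tracking, not equality.
7. **Bootstrap**: whole trials are the resampling unit (they are the
   independent units; rows within a trial are serially dependent), 1000
   replicates by default, percentile 2.5/97.5; failed replicates are
   dropped, more than half failing is an error.
8. **Exclusion screen**: two-sided exact binomial test of accuracy
   against ½ at α = 0.05; a participant indistinguishable from chance
   is excluded.

## Model comparison

Fixed (evidence-only) vs time-varying (time + evidence) wait/go models,
BIC = k·ln(n) − 2·log L with n = number of (T, X, A) rows (each wait/go
opportunity is an observation; per-trial counting is available for
sensitivity analysis). Posterior model probability under equal priors is
computed stably from ΔBIC; |ΔBIC| < 2 is reported as ambiguous.

## Pipeline presets

Six presets give the task parameters of the study designs (drifts
0.20/0 at D_C = 15, D_I = 50; 0.22/0 at D_I = 50 with D_C = D_I/3 or
D_C = D_I, at 200 ms and 50 ms ISI; 0.40/0.10 at D = 70). Easy blocks
run 240 s, difficult and mixed 300 s, two blocks per condition; a
`duration_scale` knob shrinks blocks for quick runs. The mixed condition
is compared against the easy games (against the difficult games, on
difficult-labelled mixed trials, for the moderate-drift design where
the optimal boundary rises). The cohort contrast is the per-participant
circular slope difference tested against zero with an off-the-shelf
one-sample t test, reported for parity with standard practice.

## Problem sizes used in tests

Recovery studies run at desk scale, chosen to keep the whole suite
around a minute while leaving comfortable statistical margins: slope
recovery uses 6 participants × 220 trials per cell across true slopes
{−60°, −30°, 0°} (baseline, σ_drift = 0.35 and p_attend = 0.7
variants); model-selection recovery uses 100 replicates × 150 trials
per slope; the exact-vs-Monte-Carlo check uses 10 random linear
boundaries × 1e5 trials with agreement required within 3 standard
errors (ratio-estimator SE). The Monte-Carlo comparison applies the same
horizon truncation (forced guess at t_max) to simulation and exact
evaluation, since policies whose boundary outruns the walk never cross
otherwise.

## Known limitations

- The solver assumes symmetric boundaries via the up-world-only
  propagation in policy evaluation; asymmetric priors would need
  two-world propagation (beliefs already support them).
- Boundary traces are only defined up to lattice parity; extraction
  smooths over {t, t+1} as described.
- The probabilistic agent uses |x| at the current step, whereas the
  fitted table aligns evidence to the final response; on wait rows where
  the walk's sign later flips the two differ. At realistic parameters
  the discrepancy is below the fit's sampling error (tested), but exact
  coefficient recovery is only approximate by construction.
- Nondecision-lag estimation assumes the easy-game drift is far enough
  below the 0.75 cut; for drifts near ½ ± 0.3 the window narrows.
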