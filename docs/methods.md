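# Methods

## The behavioral model

The package treats a binary intertemporal choice as a Bernoulli draw whose
probability comes from a discounted-utility model passed through a logistic
link. The immediate option keeps its face value (`v1 = r1`, delay 0); the
delayed option is multiplied by a model-specific discount factor
`f(D) ∈ [0, 1]`:

| model                 | discount factor            | free parameters |
|-----------------------|----------------------------|-----------------|
| hyperbolic            | `1/(1 + κD)`               | κ, β            |
| exponential           | `κ^D`                      | κ, β            |
| quasi-hyperbolic      | `γ κ^D` (D > 0)            | κ, γ, β         |
| hyperboloid           | `1/(1 + κD)^s`             | κ, s, β         |
| modified hyperboloid  | `1/(1 + κD^s)`             | κ, s, β         |
| double-exponential    | `w κ₁^D + (1−w) κ₂^D`      | κ₁, κ₂, w, β    |
| constant-sensitivity  | `exp(−(κD)^δ)`             | κ, δ, β         |

Delays are measured in days (generated and stored as integers, real-valued
internally), outcomes in GBP at penny granularity, signed: reward trials
satisfy `0 < r1 < r2`, loss trials `r2 < r1 < 0`. The discount factor is
sign-free, so the same machinery covers loss discounting unchanged. In the
modified hyperboloid, `s` scales the *delay* and is read as nonlinear time
perception; in the plain hyperboloid it scales the whole denominator.

Choice probabilities use `p(immediate) = 1/(1 + exp(β (v2 − v1)))` with
sensitivity β ≥ 0 (β → 0 random choice, β → ∞ deterministic). The
log-likelihood of a dataset is the sum of log predicted probabilities of
the observed choices; trials without a response are excluded.

Parameter spaces: κ ∈ [0, 10] for the hyperbolic family (an operational cap
on a conceptually unbounded rate, matching the bound used during fitting),
κ ∈ [0, 1] for the exponential family (a daily retention), κ > 0 for
constant sensitivity; γ, s, w, κ₂ ∈ [0, 1]; δ > 0 (capped at 10 for bounded
optimization); β ∈ [0, 100]. Real cohorts put most κ mass below 0.2 with a
long tail, which is why the recalibrated grids target rates down to 1e-5.

## Fitting

`fit_mle` maximizes the likelihood with bounded L-BFGS-B from 10 seeded
random starts: hyperbolic-family κ log-uniform over its range (lower edge
1e-6), β log-uniform over [0.01, 100], bounded extras uniform. Two
refinements matter in practice and were adopted after the plain scheme
demonstrably failed its oracles:

- **Rate-scale starts for retention κ.** For the exponential-family models
  the informative region is κ near 1 (`κ^D` underflows to a flat, zero-
  gradient likelihood for moderate κ and D ≥ 30). Starts are therefore
  drawn log-uniformly in the decay rate `−ln κ` over [1e-4, 10], which
  covers retentions up to ~0.9999 instead of piling into the flat basin.
- **Nested warm start.** Each >2-parameter model gets one extra start from
  its fitted 2-parameter backbone mapped onto the reduction manifold
  (hyperboloids from hyperbolic with s = 1; quasi-hyperbolic γ = 1,
  double-exponential w-collapsed, constant-sensitivity δ = 1 from
  exponential). On adaptive-run data — trials concentrated near
  indifference — all random starts can land in the wide β ≈ 0 plateau while
  the global optimum sits on a narrow ridge; the warm start finds it and
  guarantees a nesting model never fits worse than its special case.

Numerical guards: the softmax exponent is clamped at ±700 and probabilities
are clipped to [1e-12, 1 − 1e-12] inside the log — both far below any
reported tolerance. Parameters within 1e-6 (absolute) of a bound are
flagged `at_boundary`; each run and condition is fitted independently. Fits
are deterministic given the `FitConfig` seed. The suite verifies the fitter
against a dense (κ, β) grid search on seeded datasets (agreement within
1e-3 log-likelihood).

## Trial generation

**Calibration run (run A).** One trial per condition × delay × delayed
outcome × hypothetical κ, the immediate outcome at the hyperbolic
indifference point `r1 = r2/(1 + κD)` (the p = 0.5 inversion with β fixed
to 1), penny-rounded. Three built-in grids are provided: the initial
literature grid (delays {2,7,30,90,180}, outcomes ±{2,5,10,20}, κ
{0.01,0.1,0.2,0.6}; 160 trials), the recalibrated grid matching empirically
low rates (delays {7,...,365}, outcomes ±{5,...,50}, κ {1e-5,...,0.6}), and
its loss-delay extension (loss delays {30,...,1095}).

**Adaptive run (run B).** For each condition × target p₁ ∈ {0.3, 0.5, 0.7}
× delay × outcome, the immediate outcome solves
`r1 = v2 + ln(p1/(1−p1))/β` at the subject's fitted parameters, then is
penny-rounded (half away from zero; atypicality is judged on the rounded
value, since the displayed stimulus is currency). The offset `ln odds/β` is
constant across delays, so all of a subject's trials at one level are
equally far (in value) from their indifference curve. β = 0 makes the
inversion undefined; the generator raises and leaves the fallback to the
caller.

**Atypical-trial resolution.** Extreme parameters can produce candidates
that are sign-violating (case 1), equal to the delayed outcome (case 2) or
beyond it in magnitude (case 3). The delay is stepped one day at a time —
decreased for case 1 (raising the discounted value raises r1), increased
for cases 2–3 — re-solving at each step until valid or the sweep bounds
(the condition's smallest/largest grid delay by default) are reached. Each
transition preserves the step direction, so the sweep terminates. Unresolved
candidates fall back to penny surgery: case 1 → r1 = ±£0.01; case 2 → one
penny toward zero; case 3 (no canonical fallback exists) → clamped one
penny inside r2. Resolved trials always satisfy the smaller-sooner
structure; resolving an already-valid trial is a no-op, and any change sets
the `adjusted` flag. Trial order is randomized within alternating
40-trial condition blocks with a recorded seed.

## Synthetic agents

`sample_population` draws per-condition parameters from configurable
marginals. Defaults emulate the qualitative features of human cohorts:
a bimodal rate distribution (90% log-uniform on [1e-5, 0.6] for the
dominant low-rate mode, 10% uniform on [7, 10] for a minority of extreme
discounters) for the hyperbolic family; retention-scale defaults near 1 for
the exponential family; s ∈ [0.2, 0.8]. Reward and loss parameters share
marginals and are coupled by a Gaussian copula with rank correlation 0.5 by
default — enough linkage to exercise cross-condition analyses without
asserting any particular empirical correlation. Choices are Bernoulli draws
from the agent's own link; missing responses, if requested, are uniform at
a configurable rate (real missingness is surely not uniform, but no
mechanism is specified by the task). Reaction times are not modeled; RT
columns exist only so observed data can carry them.

What passing simulations do **not** show: real subjects are not stationary
softmax discounters — lapses, magnitude effects, risk attitudes and model
heterogeneity are all outside the generator, so recovery results bound what
the *machinery* can do, not what a human study will yield.

## The recovery loop and its two frequency readings

`parameter_recovery` runs the full loop per agent (simulate run A → fit →
generate run B → simulate → refit) and reports true-vs-estimated
correlations plus the observed immediate-choice frequency at each target
level, in two variants:

- **observed** — the true agent's choices on trials built from *estimated*
  parameters. This includes estimation error: when calibration data are
  nearly separable, β is overestimated, offsets shrink, and realized
  probabilities compress toward 0.5 at the outer levels.
- **self_consistent** — choices drawn from the trial-generating parameters
  themselves. This isolates the inversion + rounding + resolution
  machinery, whose only distortions are penny granularity and fallback
  trials; it is the reading against which binomial calibration (within
  sampling error of 0.3/0.5/0.7) is asserted in the tests.

Both are reported side by side in the acceptance output; the gap between
them is a measure of calibration-run informativeness, and is exactly the
lever the iterative grid recalibration is designed to close.

## Problem sizes and determinism

The test suite and acceptance script use 50-agent populations, 50-replicate
model comparisons, 1,000-draw inversion suites and 10,000-evaluation
identity checks — sizes at which every stochastic criterion has comfortable
margin while the whole suite runs in minutes on one CPU. Every random step
(population sampling, choice simulation, trial-order shuffling, optimizer
starts) is driven by an explicit seed; derived seeds come from
`numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

- Group-level inferential statistics (signed-rank tests, correlation
  comparisons) are deliberately out of scope; the reports emit tidy tables
  for external tools.
- β at the zero boundary has no principled inversion; the generator refuses
  rather than guessing.
- The κ/s trade-off in the hyperboloid models is weakly identified at 80
  trials per condition; boundary flags and cross-run correlations in the
  recovery report are the intended diagnostics.
- The weighted prediction summary averages the two observed-choice classes
  equally (flagging when a class is absent); weighting by class size is the
  plausible alternative and is trivial to compute from the reported counts.
- Penny granularity bounds how precisely a target probability can be hit
  when β is large (offsets below £0.005 round away).
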