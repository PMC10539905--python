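# Methods

## Model

Subjects occupy one of three live sarcopenia stages — no sarcopenia
(1), possible sarcopenia (2), sarcopenia (3) — or death (4), and move
between them in continuous time.  The process is Markov with
time-inhomogeneous generator `Q(a, z)`: each allowed transition r→s has
intensity

    q_rs(a, z) = exp(α_rs + β_rs (a − 60) + γ_rs·z)

with `a` current age in years, 60 the centering age (so `α_rs` is the
log rate per year at 60), and `z` time-constant covariates.  Positive
`β_rs` gives Gompertz-type exponential ageing of the rate.  The default
transition structure is the severity ladder 1↔2, 2↔3 plus death from
every live state; two-year observed 1→3 or 3→1 jumps are explained by
passage through the unobserved intermediate stage.  Direct 1↔3
intensities can be enabled (`adjacent_structure(direct_1_3=True)`)
when the ladder assumption is in doubt.

### Assumptions

* Markov: future evolution depends only on the current stage and age
  (no duration-in-state or frailty effects).
* Log-linear age dependence; within any computation interval the
  intensities are frozen at the interval's start age (piecewise-
  constant approximation).
* Covariates act proportionally on every intensity they enter;
  subgroup analyses can instead refit the model per stratum, which
  drops the proportionality assumption at the cost of power.
* Staging is error-free: no misclassification layer.

## Likelihood

Panel observations give, per subject, states at interview ages; the
path between interviews is unobserved.  A live→live interval of length
Δ starting in r and ending in s contributes `P_rs(Δ)`, where `P` chains
matrix exponentials of `Q·h` over sub-steps of length `approx_step`
(default 1 y, last sub-step partial).  A death at exact age `t_D`
contributes the density `Σ_{s live} P_{r,s}(t_D − t_0) · q_{s,4}(t_D)`.
Deaths reported without an exact date are interval-censored between
the last-alive wave and the reporting wave; their time is imputed at
the midpoint of the two wave times and then treated as exact — the
convention matching the emulated survey, whose later waves did not
record death dates.  The midpoint is nearly unbiased when deaths fall
roughly uniformly within the two-year gap (verified by simulation in
the test suite: |mean error| < 0.1 y).

Maximisation is BFGS on the unconstrained (α, β, γ) scale with
finite-difference gradients, initialised at crude rates (observed
transition counts over person-time at risk, floored at e⁻⁸/y for
unobserved transitions) and zero slopes.  The covariance is the
inverse observed information from a central-difference Hessian at the
MLE; transitions never observed in the data are flagged as weakly
identified.  The convergence tolerance is `gtol = 5e-4` on the
gradient norm: with |loglik| of order 10³–10⁴ and finite-difference
gradients, tighter thresholds chase difference noise; at this setting
parameter error from residual gradient is orders of magnitude below
one standard error.

### Numerical core

Matrix exponentials of the 4×4 generators are computed by a batched
scaling-and-squaring Padé-13 routine (`_linalg.expm_batch`) — one call
per likelihood evaluation over all sub-steps of all intervals — with a
shared squaring count taken from the batch's largest norm.  It is
cross-checked against `scipy.linalg.expm` in the tests; `scipy`'s
routine is not used in the hot path only because it has no batched
form.  The intensity exponent is clipped at 30 (rates ≤ e³⁰/y) so the
optimizer can wander without overflow.

## Life tables

Conditional life expectancy in live state s given live state r at age
x is

    e_rs(x) = ∫_x^ω P_rs(x, a) da,       ω = 120 y

with occupancy `P(x, a)` chained over a half-step grid (resolution
`h/2`).  Three quadratures share that single occupancy computation:

* `step` — left-endpoint Riemann sum, `h Σ_k P(a_k)` (first-order; its
  error for a survival-type integrand is ≈ `h/2 · (P(x) − P(ω))`, so it
  systematically overestimates by a fraction of `h`);
* `middle_riemann` — midpoint rule (second-order);
* `simpson` — composite Simpson on each h-interval using its midpoint,
  i.e. `(h/6)(P(a_k) + 4P(a_k+h/2) + P(a_{k+1}))`.  Because each
  h-interval carries its own midpoint, the rule is well-posed for any
  number of intervals; the classical even-interval restriction never
  arises.

Default `h = 0.5` y, exposed in `LEConfig`; closed-form comparisons in
the tests use `h = 0.02`, where all three rules agree with the exact
integral of a constant-mortality model to better than 0.02 y (at
`h = 0.1` the left-endpoint rule alone would still be ≈0.05 y high —
the price of its first-order accuracy, not a bug).

Marginal life expectancies weight the conditional rows by the baseline
state distribution at x: a multinomial logit of baseline stage on
(age − 60), the smoothed default, or the raw baseline proportions
(`weight_mode="empirical"`).  NSLE/PSLE/SLE are the prevalence-weighted
years in states 1/2/3 and TLE their exact sum.

Uncertainty: parametric bootstrap with `B = 30` draws (the default
mirrors the three-way sensitivity-analysis convention of the
re-implemented estimator) from N(θ̂, Σ̂), full table recomputed per
draw; 95% intervals as 2.5/97.5 percentiles, with a normal
approximation (mean ± 1.96·SD) also available since percentiles from
30 draws are coarse.  A non-PSD covariance is repaired by eigenvalue
clipping and logged.  Draws are bit-reproducible given the seed.

## Synthetic cohorts

The generator emulates a CHARLS-like national ageing panel: n subjects
(default 3,000), baseline ages uniform on 60–90, baseline stage drawn
from an age-dependent multinomial logit, trajectories simulated by
exact competing-risks sampling on 0.25-y piecewise-constant age
segments, three interview waves at 0/2/4 y with ±0.3 y uniform jitter,
absorbing per-wave dropout (8%), and deaths reported exactly dated
with probability 0.5, otherwise interval-censored at the next attended
wave.  Raw anthropometrics can be emitted per live observation by
sampling each component uniformly inside the region its target stage
occupies (inverting the ASM equation for body weight), which makes the
staging round trip exact by construction.

The default true intensities (per year at 60: q12=0.16, q21=0.14,
q23=0.085, q32=0.17, q14=0.006, q24=0.014, q34=0.032; age slopes
+0.03/−0.02/+0.04/−0.02/+0.08/+0.075/+0.07) are illustrative, chosen
so that two-year transition frequencies show the qualitative pattern
of an ageing community cohort — onset more common than recovery from
sarcopenia, mortality ordered q34 > q24 > q14 — and a total LE at 60
near 19 y.  They are not fitted to any survey.

What the generator does **not** emulate: survey sampling weights and
household clustering, staging misclassification, informative dropout
(attrition is independent of state), covariate effects on intensities
(available in the model but off by default), and a realistic
right-skewed baseline age pyramid (uniform ages make the synthetic
baseline older, hence more sarcopenic, than a real survey).  Passing
tests therefore demonstrate correctness of the estimator chain under
the stated model, not robustness to these real-data features.

## Numerical and design choices

* Interview dates known to year+month are placed at day 15; ages are
  day differences / 365.25.  Worst-case dating error ≈ 0.04 y.
* Sub-step length `approx_step = 1 y` in the likelihood balances the
  freezing bias of start-age evaluation (noticeable over 2-y intervals
  when mortality slopes are ~0.08/y) against expm count; refining the
  step monotonically converges the log-likelihood (tested).
* Zero-probability observed transitions make the log-likelihood −∞;
  `loglik_breakdown` names the offending records instead of failing
  silently.  The optimizer sees a large finite penalty.
* Ties/degenerate inputs: a prevalence fit with zero age variance
  drops the age column (saturated intercepts = observed proportions);
  a live stage absent at baseline is a hard error naming the stage;
  chi-squared tables with a zero margin are rejected naming the row or
  column.
* Boundary conventions in staging are literal: strength and mass use
  strict `<`, chair stand uses `≥`.  Low performance alone maps to no
  sarcopenia by default, with the broader screening variant behind
  `possible_includes_low_performance`.
* Severe sarcopenia is deliberately not a state: three live stages
  keep every stage identifiable from two-to-three-wave panels.

## Problem sizes

The test suite and the acceptance script use n = 3,000 subjects ×
3 waves for the recovery study (≈7,000 intervals, 14 free parameters),
10,000 Monte-Carlo paths for the trajectory-sampling checks, and
h = 0.02 grids for closed-form quadrature comparisons — sizes at which
every asserted tolerance has comfortable Monte-Carlo margin while a
full run stays in the low minutes on a single core.

## Known limitations

* No hidden-Markov misclassification layer; staging noise biases
  transition rates toward overestimated movement.
* Time-inhomogeneity is limited to log-linear age; no calendar-period
  effects, no frailty.
* With B=30 bootstrap draws the percentile CI endpoints are order
  statistics of a small sample; coverage is approximate (the test
  suite asserts containment of the truth in a recovery study, not
  exact coverage).
* The interval-censored-death midpoint convention slightly biases
  death ages late when mortality rises steeply within a wave gap.
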