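# sarcolife

Multistate modelling of sarcopenia progression and life expectancy in
ageing cohorts.

Sarcopenia — age-related loss of skeletal muscle mass together with low
strength and/or low physical performance — is a dynamic condition:
older adults move between *no sarcopenia*, *possible sarcopenia* and
*sarcopenia*, recover, deteriorate, and die, while surveys observe them
only at interview waves a couple of years apart.  `sarcolife` is a
library for epidemiologists and biostatisticians who want to turn such
interval-censored panel data into transition rates and into life
expectancies with and without sarcopenia.

The pipeline covers:

* **Staging** (`sarcolife.staging`) — AWGS-2019 classification from raw
  anthropometrics.  Appendicular skeletal muscle mass (kg) is estimated
  from the validated equation
  `ASM = 0.193·weight + 0.107·height − 4.15·sex − 0.037·age − 2.631`
  (sex: man=1, woman=2) and height-adjusted to ASM/Ht² (kg/m²).  Low
  grip (<28/18 kg man/woman), low ASM index (<7.0/5.4 kg/m²), and slow
  or failed five-time chair stand (≥12 s) combine into the three live
  stages.
* **Cohort construction** (`sarcolife.cohort`) — decimal ages from
  year+month interview dates (mid-month convention, 365.25 d/y),
  midpoint imputation of interval-censored death times, and panel
  validation.
* **Multistate model** (`sarcolife.msm`) — a continuous-time Markov
  model with log-linear (Gompertz-type) intensities
  `q_rs(a) = exp(α_rs + β_rs (a − 60) + γ_rs·z)` on a severity-ladder
  structure (1↔2, 2↔3, death from every live state), fitted by maximum
  likelihood to interval-censored live transitions and exactly timed
  deaths via piecewise-constant matrix exponentials.
* **Life tables** (`sarcolife.lifetable`) — multistate life-table
  integration `e_rs(x) = ∫ₓ^ω P_rs(x,a) da` (ω = 120 y) with `step`,
  `middle_riemann` and `simpson` quadratures, baseline-prevalence
  weighting via a multinomial logit in age, and parametric-bootstrap
  95% intervals (30 draws by default).  Outputs NSLE, PSLE, SLE and
  TLE: years expected without sarcopenia, with possible sarcopenia,
  with sarcopenia, and in total.
* **Synthetic cohorts** (`sarcolife.synthetic`) — a generator with
  known ground truth (baseline ages 60–90, three jittered waves ~2 y
  apart, dropout, mixed exact/interval-censored deaths) so the whole
  chain is testable end to end.
* **Descriptive tables** (`sarcolife.report`) — prevalence-by-
  characteristic tables with chi-squared tests and wave-to-wave
  transition matrices with pooled deterioration/improvement shares.

## Worked example

`examples/03_life_expectancy.py` simulates a 1,500-subject cohort from
known intensities, refits the model, and reports life expectancies at
age 60:

```
years expected in each state from age 60 (95% CI):
  NSLE    5.50  ( 3.57 -  6.06)
  PSLE    8.30  ( 6.53 -  8.86)
  SLE     5.84  ( 4.49 -  6.59)
  TLE    19.64  (14.81 - 20.52)

conditional on the starting state at 60, total LE is:
  start in state 1:  20.79 y
  start in state 2:  19.09 y
  start in state 3:  17.51 y

true TLE of the generating model: 19.07 y
```

A 60-year-old drawn from this cohort's baseline state mix expects 19.6
years of life, of which 5.8 would be lived with sarcopenia; starting
already sarcopenic at 60 costs about 3.3 years relative to starting
non-sarcopenic.  The estimate brackets the generating model's true
value (19.07 y) well inside the bootstrap interval.  The other example
scripts cover staging raw measurements, parameter recovery, and the
descriptive tables.

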