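# Methods

## The decision problem

`qmcea` implements a long-term cost-utility analysis of manualised systemic
family therapy (FT) added to treatment as usual, versus treatment as usual
alone (TAU), for adolescents seen by mental-health services after repeated
self-harm.  The evidence base is a two-arm randomised trial (the SHIFT trial,
398 vs 397 analysable participants) whose 18-month questionnaire follow-up
(EQ-5D-3L utilities, self-reported non-hospital resource use) was extended to
60 months of linked hospital-episode records.  Costs take the NHS and
Personal Social Services perspective, in GBP; health benefit is measured in
quality-adjusted life years (QALYs).

## The quasi-Markov model

Time is divided into ten 6-month cycles (months 0–60).  Each cycle a cohort
member occupies exactly one of three states:

* **RSH** — at least one self-harm hospitalisation during the cycle
  (base case; a secondary analysis uses *any* hospitalisation);
* **non-RSH** — alive with no qualifying hospitalisation;
* **death** — absorbing.

Unlike a conventional Markov cohort model there is no transition matrix:
the probability of occupying the RSH state at cycle *c* is predicted directly
from a logistic regression of the cycle-level hospitalisation indicator, and

    pi_RSH(c)    = P(event at c | alive) * (1 - pi_death(c))
    pi_nonRSH(c) = 1 - pi_RSH(c) - pi_death(c)

with `pi_death` a Kaplan–Meier product-limit estimate.  Because state
membership is re-predicted each cycle rather than propagated, the model has
no memory of earlier self-harm episodes; this mirrors the data-generating
regressions and is a known limitation (cycle-to-cycle dependence of self-harm
is not represented).

A death during cycle *c* is placed at time *c* + 0.5 on the cycle axis, so it
affects occupancy from cycle *c* + 1 onward.  Death contributes zero cost and
zero utility (standard convention).

### Cycle payoffs

With SH-status-conditional predictions (see below), expected cost in a cycle
for one arm is

    E[cost] = [ P(SH) * E[cost_SH]
              + (P(SH) * P(nonSH | SH) + P(noSH) * P(nonSH | noSH)) * E[cost_nonSH]
              + P(SH) * P(nh | SH) * E[c_nh | SH]
              + P(noSH) * P(nh | noSH) * E[c_nh | noSH] ] * (1 - pi_death)

(`nh` = any non-hospital cost occurring), plus the per-arm intervention cost
split equally over cycles 0–1.  Under the any-hospitalisation state
definition the hospital part collapses to `P(any) * E[cost_any]`.  Expected
utility is `pi_RSH * u_SH + pi_nonRSH * u_noSH`, and the QALY contribution is
utility × 0.5 years.  Non-hospital costs are observed only inside the trial
window; beyond month 18 they are extrapolated through the SH-status-
conditional occurrence and magnitude models (a config flag zeroes them for
the one-way analysis).

### Discounting

Costs and QALYs are discounted at an annual rate *r* = 3.5% (NICE reference
case) with weight `(1 + r)^(-c/2)` at the start of cycle *c*; no half-cycle
correction is applied.  Discounting from the cycle midpoint or end is exposed
in config (`discount_from`) and changes totals by under 2%.  Totals are
reported at the 18-month (cycles 0–2) and 60-month (cycles 0–9) horizons.
Intervention costs, incurred in the first year, enter undiscounted within
their cycles.

## Estimation

Nine regressions are fitted as generalized estimating equations clustered on
patient, with robust sandwich covariances: binomial-logit models for the
probabilities (SH hospitalisation; any hospitalisation; non-SH
hospitalisation given SH status; non-hospital cost occurrence given SH
status), gamma-log models for the conditional cost magnitudes, and a
gaussian-identity model for EQ-5D utility given SH status.  The design in
every model is intercept + baseline covariates (gender, age group, index
hospitalisation cause, hospital-referral flag) + cycle dummies + saturated
arm × cycle interaction dummies.  The working correlation defaults to
independence (exchangeable is available); with independence and a gaussian
identity family the point estimates coincide with ordinary least squares,
which the tests exploit as an oracle.

Interaction and time dummies whose pooled Wald tests have p ≥ 0.05 are pruned
to shared coefficients by batch backward elimination; hospital-cost models
always retain all arm × time interactions.  In sparse logistic fits a dummy
whose outcome cell is empty is dropped (the cell borrows the reference
coefficient); divergence on a substantive covariate raises a separation
error.

"Average participant" predictions evaluate the linear predictor at the sample
covariate means and invert the link; this is a linear-predictor-scale
standardisation, an approximation to population-averaged values.  Models fit
only on the trial window (utility, non-hospital costs) carry their last
observed cycle's coefficients forward, matching the flat post-trial grids of
the source regressions.  Prediction outside cycles 0–9 is an error — the
record linkage spans the model horizon, so no extrapolation is permitted.

Mortality uses a Kaplan–Meier estimate per arm with a log-rank comparison
(two deaths among ~800 patients are far too few for regression modelling).

## Missing data

Within-trial utilities and self-reported costs are missing for patients who
stop returning questionnaires (assumed monotone); hospital indicators have
sporadic small gaps; and the record linkage ends at a patient-specific
censoring cycle, which truncates the panel (censoring, not imputation,
handles differential follow-up length — GEE accepts the unbalanced panel).

Missing trial-window values are multiply imputed (default M = 100) by
predictive mean matching: a linear model on complete cases, a coefficient
vector drawn from its asymptotic normal ("proper" imputation), and a donor
drawn uniformly from the k = 5 observed cases with nearest predicted mean.
Donor values are observed values, so utilities stay below 1, costs stay
non-negative, and binary indicators stay binary without post-processing.
Conditional costs are imputed only where the (already-completed) event
indicator is 1 and are zero otherwise.

The default imputation ordering completes the near-complete hospital-record
fields first, then utilities and non-hospital costs by time, each model using
all previously completed variables as predictors.  Ordering utilities first
was tried and rejected: utilities were then imputed without the SH indicator
and the state–utility contrast attenuated markedly (fitted u_SH drifted from
0.674 toward the overall mean).  When the pattern is not monotone in the
declared ordering a warning is raised and a second, chained pass re-imputes
each variable with all others complete.

Analysis models are fitted within every imputed dataset and pooled by
Rubin's rules — pooled coefficient vector is the mean, pooled covariance is
`W + (1 + 1/M) B` with `B` the between-imputation covariance — with a
Satterthwaite-type degrees of freedom per coefficient.

## Cost-effectiveness summary and uncertainty

Deterministic results report per-arm discounted totals, incremental cost ΔC
and QALYs ΔQ, the ICER ΔC/ΔQ with dominance labels (dominated: ΔC > 0 and
ΔQ < 0; dominant: the reverse), and net benefits INHB(λ) = ΔQ − ΔC/λ and
INMB(λ) = λ·ΔQ − ΔC.

The probabilistic sensitivity analysis (default 10,000 simulations) draws
each model's coefficient vector from a multivariate normal with the pooled
mean and covariance on the link scale (an eigendecomposition square root;
non-PSD covariances are repaired to the nearest PSD matrix with a warning),
re-runs the Markov engine per draw through a vectorised path that is exactly
the deterministic computation when the covariance is zero, and records
(ΔC, ΔQ) at both horizons.  Draws use one substream per model filled
row-major, so enlarging the simulation count never changes earlier draws.
Drawn utilities are truncated at 1.  The acceptability curve is the fraction
of draws with positive INMB on a willingness-to-pay grid of GBP 0–50,000 in
steps of 500; the CE plane reports compass-quadrant counts.

An alternative value set replaces the empirical cost/utility models with the
NICE evidence-review parameters: state utilities 0.93 (non-RSH) and 0.68
(RSH) with Beta uncertainty, and a per-cycle RSH excess cost of GBP 2,134
(mean of Gamma(shape 4, scale 533.38)).  In this mode the PSA draws the state
values from their Beta/Gamma distributions while the state-probability model
still uses coefficient draws.

One-way scenario toggles: remove mortality, set the discount rate to zero,
zero the post-trial non-hospital costs, switch the state definition to any
hospitalisation, and the NICE value set.

## The synthetic-trial generator

No public dataset exists (the hospital records sit under an NHS Digital
sharing agreement), so the generator emulates the cohort from the published
cycle-level grids, which are the generator defaults: per-cycle SH
hospitalisation probabilities per arm declining from 43–47% to 6–8%;
non-SH hospitalisation probabilities conditional on SH status (33.8% → 8.7%
given SH, 26.8% → 6.4% without); conditional cost means per arm and cycle;
non-hospital cost occurrence probabilities (flat at 87.9%/77.3% beyond the
first year) and magnitudes (GBP 933.35 / 705.03 by SH status); state
utilities 0.674 / 0.792; a death hazard yielding about two deaths per
cohort, all in the FT arm; ~50% questionnaire response; and a censoring
distribution leaving ~40% of patients with complete 60-month records.

Generator design choices:

* Covariates (85% female, 45% aged 11–14, 60% index self-poisoning, 55%
  hospital-referred) are sampled independently — plausible margins for a
  hospital-presenting adolescent self-harm cohort; no joint distribution is
  published.
* Conditional costs are gamma draws with fixed shape (1.5 for hospital,
  2 for non-hospital costs — strongly right-skewed, as health-cost data are)
  and scale set per cell from the mean grids.
* Utilities are truncated-normal draws (s.d. 0.20) on the EQ-5D-3L tariff
  range [−0.594, 1], with the location solved so the *truncated* mean equals
  the configured state mean; naive truncation at the ceiling would bias
  realised means ~0.05 low and break moment recovery.
* Deaths are an absorbing per-cycle hazard at cycle granularity.
* One master seed; every operation draws from its own derived substream, so
  stages are independently reproducible.
* Per-patient intervention costs are config inputs (the micro-costing
  worksheets are not public); the defaults (FT GBP 1,800, TAU GBP 300 over
  the first year) were sized from the published incremental-cost scale of
  roughly +GBP 1,700 for FT.

What the generator does **not** emulate: raw episode records or ICD coding
(events enter at the cycle-indicator level), cycle-to-cycle dependence of
self-harm within patient, covariate effects on event rates (offsets default
to zero), therapist-level clustering, or carer outcomes.  Passing tests
therefore demonstrate that the pipeline recovers the published parameter
structure under the model's own assumptions — not that those assumptions hold
in the real cohort.

## Numerical choices

* GEE convergence: relative coefficient change < 1e-8, at most 100
  iterations; non-finite estimates raise an error.
* Rank-deficient designs are reduced by pivoted QR before fitting.
* Occupancy rows must sum to 1 within 1e-12; combined probabilities outside
  [0, 1] raise rather than clip.
* ICER with ΔQ = 0 and ΔC ≠ 0 is reported as a signed-infinity label and
  excluded from ratio summaries.
* PMM requires at least k observed donors and errors naming the variable
  otherwise.

## Problem sizes used in the shipped checks

The test suite exercises the full cohort size (398 + 397, 10 cycles) with
M = 10 imputations and 2,000 PSA draws for the end-to-end qualitative check,
100 replicate cohorts for parameter recovery, and 40 replicates at 200
patients/arm for the pooled-difference coverage study; the acceptance script
computes desk-verifiable arithmetic from the published tables.  The default
configuration (M = 100, 10,000 draws) is used for full analyses.

## Known limitations

* State probabilities are predicted independently per cycle: no tunnel
  states, no event memory, no lifetime horizon.
* The covariate-mean standardisation is not a true population average over
  the covariate distribution (differences are small with a logit link and
  these covariate spreads).
* The two observed deaths cannot distinguish chance from effect; using the
  FT-estimated hazard may understate the TAU arm's benefit if the mortality
  signal is real.
* Imputation treats the trial window only; post-trial non-hospital costs are
  model-extrapolated, not imputed.
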