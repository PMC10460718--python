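# Methods notes

## Scope and data

The package re-implements a pooled population PK and PK/PD analysis of
bempedoic acid and LDL-C. The original clinical datasets are not available,
so the pipeline runs on synthetic cohorts whose statistical structure mirrors
the pooled population, and the published final-model parameter tables are
treated as ground truth for worked examples and parameter-recovery
experiments. Everything the pipeline reports is computed at run time from
those parameters and from data the cohort generator produces.

## Event tables and exclusions

Records follow the usual longitudinal convention: one row per dose or
observation with subject ID, time (decimal hours since the subject's first
dose; all rate constants are per hour), amount, observed value, an
observation-type code (PK concentration in µg/mL or LDL-C in mg/dL), and
event/missing flags, plus one column per subject covariate. Exclusion
filters reproduce the analysis-set rules: subjects below the dosing-compliance
threshold (default 80%) are removed wholesale; PK observations before the
first dose are removed; post-dose PK observations below the quantification
limit (default 0.01 µg/mL, the lower end of the assay range) are removed
rather than modeled by censored likelihood. Pre-dose LDL-C observations are
retained — they define baseline; the pre-dose exclusion concerns drug
concentrations only. The exclusion report exposes the below-quantification
fraction with both possible denominators (all observations, or post-dose PK
observations) because the convention is ambiguous in summaries of this kind.
Placebo subjects carry an arm label and zero-amount dose records; their drug
concentration is identically zero downstream.

## PK model

Dose enters a single transit compartment that empties into the central
compartment at rate Ka — one first-order pre-systemic step, the minimal
structure consistent with a "single transit compartment" diagram, since a
separate transit rate would not be identifiable. Disposition is
two-compartment with linear elimination; parameters are apparent (CL/F,
Vc/F). The linear three-state system is solved in closed form by
partial fractions over the three exponents (the two disposition roots and the
absorption rate); near-coincident exponents are separated by a relative
nudge of 1e-6, well below solver tolerances but enough to keep the
partial-fraction coefficients finite. The closed form is verified against
adaptive ODE integration at 1e-8 relative accuracy, and multi-dose profiles
are superposed dose by dose (vectorized over doses and subjects, chunked to
bound temporaries).

Covariate effects: power models for continuous covariates, proportional
shifts for indicators, multiplying when several target one parameter.
Reference values are not printed in the source tables; continuous covariates
are centered at the population medians (weight 83.7 kg, age 62 y, eGFR 89.3
mL/min), and the reference subject is a fasted white male healthy
non-diabetic taking no concomitant lipid-modifying therapy. The fed state
acts on Ka per dose (a record-level state, not a subject attribute).
Interindividual variability is log-normal, with %CV = sqrt(exp(ω²)−1)·100.
Residual error is log-additive; reported residual percentages are interpreted
as approximately the SD of the log-scale error times 100.

Steady-state exposure uses the linear-PK identity AUC_ss = F1·dose/(CL/F)
with Cavg,ss = AUC_ss/24 for once-daily dosing; this matches trapezoidal
integration of the simulated steady-state profile to well under 0.1%.

## PD model

Type-1 indirect response: zero-order LDL-C production k_in inhibited by an
Emax function of concentration, first-order loss k_out; at baseline the
system is at steady state, so k_in = k_out·baseline. Drug effect sits on
production (inhibition of synthesis), not on loss. The turnover time
1/k_out is parameterized directly in hours (TURN). Covariate effects on Imax
and baseline LDL-C follow the PK conventions; because Imax is a fraction, a
covariate-shifted typical Imax is clipped to [0, 1] with a logged warning.
During estimation the individual-level Imax (typical × e^η) is deliberately
**not** clipped: a hard clip makes the per-subject objective kinked and flat
in η, which destabilizes the Laplace mode search and its curvature; at the
fitted variabilities, η excursions past 1 are vanishingly rare, so the smooth
relaxation is numerically important and statistically immaterial.

Simulation integrates the ODE with LSODA at 1e-8/1e-10 tolerances. For
estimation, where exposure is fixed per subject, the linear time-varying ODE
is instead solved exactly by its integrating factor on a shared time grid
(2 h steps), so each objective evaluation costs one cumulative trapezoid.

Time to steady state is reported at trough (pre-dose) resolution: the
whole-day variant returns the first dosing day whose trough drop reaches the
requested fraction of the asymptotic drop, matching how trial visits are
scheduled; the continuous variant interpolates on an hourly grid. Continuous
relaxation alone reaches 99% in about 16.5 days; PK onset and the trough
convention land the whole-day answer at 18 days.

## Synthetic cohorts

Covariate marginals target the published demographic summary: 59.3% male,
age 60.5 ± 12.3 y (18–89), weight 85.1 ± 17.3 kg (42.5–160), eGFR 91.4 ±
24.5 mL/min, race 89/9/1/1% white/Black/Asian/other, 16% diabetic, 8%
healthy. Only marginals are published, so joint structure is a minimal
documented choice: the female weight mean sits 10 kg below the male mean
(the male mean is raised so the mixture keeps the target marginal), and eGFR
declines 0.8 mL/min per year of age with residual SD chosen to preserve the
marginal SD. Concomitant-therapy frequencies (35/15/30/20% none/low/
moderate/high statin intensity, 15% ezetimibe) are plausible for this mixed
phase-1/2/3 population and are free parameters of the spec. Baseline LDL-C
is generated from the PD model's typical value with its covariate effects and
log-normal variability, which reproduces the pattern that on-statin patients
start lower.

Designs: the serial schedule takes 12 samples over 0–72 h post-dose
(phase-1-like); the sparse schedule 1–2 samples per visit at randomized
clock times on visit days 14/28/56/84 (phase-3-like). LDL-C visits are
baseline then days 29/57/85; an early-visit subset (default 20%) adds days
4/8/15/22, emulating the phase-1/2 component that makes turnover
identifiable — in a pure phase-3 design the first post-baseline sample is
already at near steady state. A configurable fraction of treated subjects
(default 33%) carries no PK samples. Observations are generated with the
model's own variability and error structure; concentrations below the LLOQ
are flagged. What passing tests on these cohorts do **not** show: robustness
to model misspecification, covariate correlation structures beyond the two
induced ones, dropout, or assay artifacts in real data.

## Estimation

The objective is −2× the log marginal likelihood with each subject's
random-effect integral approximated by a second-order Laplace expansion
around the empirical-Bayes mode. Inner mode search is damped Gauss–Newton
(residual Jacobians by central differences in η, exact finite-difference
gradients of the joint density, backtracking on increase); the log-determinant
term uses a full central finite-difference Hessian of the joint density at the
mode (step 1e-3). With all random effects removed the objective reduces
exactly to the residual density at the typical predictions. The Laplace value
is validated against an adaptive Gauss–Hermite quadrature oracle on small
problems (within 0.1 OFV units on a near-linear toy, 0.5 across a parameter
grid).

Fixed effects are estimated on the log scale (positivity), covariate-shift
coefficients on the natural scale bounded below by −1, variances as
log-variances. The outer optimizer is L-BFGS-B with numerical gradients;
convergence at relative objective change 1e-10 / projected gradient 1e-3,
500 iterations maximum. The covariance of estimates is the inverse of a
central finite-difference Hessian of the objective at the optimum with step
1e-3 on the transformed scale — above the inner-approximation noise floor,
below the scale on which the surface is non-quadratic; non-positive implied
variances are reported as missing rather than truncated. Percent RSE,
correlation matrix, and the condition number of the correlation matrix
(largest/smallest eigenvalue) are derived from it. One residual SD is
estimated per fit; the simulator distinguishes serial and sparse sampling
SDs, and fits are run within a design.

Sequential PK→PD conditioning: exposure profiles are fixed per subject from
empirical-Bayes PK parameters (a frozen "post hoc" evaluation when the PK
model is known, a fitted model otherwise); treated subjects without PK data
use the population-typical profile implied by their covariates; placebo
subjects use zero. A dataset with no exposure contrast (all placebo) raises
an identifiability error rather than returning an arbitrary Imax.

Parameter-recovery experiments use 100-subject cohorts. The PK experiment
uses the serial design after a single 180 mg dose. The PD experiment pools
four dose arms (60/120/180/240 mg, matching the dose range of the pooled
program) because a single dose level leaves Imax and IC50 nearly ridge-
confounded at steady state; it uses rich PK sampling so the empirical-Bayes
conditioning step does not bias Imax through shrinkage, mirroring the
well-conditioned limb of the sequential approach.

## Covariate selection

Backward elimination removes, at each step, the candidate whose removal
raises the objective least while below the χ²(1) α = 0.001 threshold
(10.828); forward selection adds the largest qualifying decrease; ties break
on the smallest candidate index. Both operate through an abstract refitter,
so they run identically against the NLME engine and against analytic test
models. The Wald Approximation Method scores all 2^k covariate sub-models:
the objective of a sub-model that fixes coefficient subset e to zero is
approximated as OFV_full + θ̂_e'Σ_ee⁻¹θ̂_e with Σ the full-fit covariance, and
models are ranked by SBC = −½(OFV_full + Wald) − ½p·ln(n_obs), larger better,
with p the retained covariate-coefficient count and n_obs the number of
observations (both conventions — coefficient-only p, observation-count n —
are documented choices; the source names the criterion without a formula).
The top-m models (default 15) are refit exactly. On linear-Gaussian models
the quadratic approximation is exact and the WAM ranking reproduces the
exact-refit ranking, which the tests assert; the pre-selection screen drops
coefficients with |estimate| < 0.1 or |estimate|/SE ≤ 2.

## Evaluation

The VPC simulates replicate datasets on the observed design (each subject's
dosing, sampling times, covariates) and compares observed 5th/50th/95th
percentiles per time bin with the 90% band of the same percentile across
replicates. Bins default to deciles of observation time; percentiles use
linear (type-7) interpolation; the prediction-corrected variant rescales by
bin-median population prediction. Health checks flag |correlation| > 0.95
between estimates and correlation-matrix condition numbers > 1000. Residual
tables provide population and individual weighted residuals (the population
weighting uses the residual SD at the population prediction, not a full
first-order covariance) and per-parameter empirical-Bayes shrinkage
1 − SD(EBE)/ω.

## Forest simulations

Each of (by default) 100 iterations resamples complete covariate vectors
with replacement — preserving within-subject covariate correlation — draws
fixed effects from a multivariate normal at the estimates with the estimation
covariance (draws violating positivity or proportional-shift bounds are
rejected and redrawn, with the rejection count logged), draws individual
random effects, and computes per-subject metrics: steady-state AUC for PK,
and percent LDL-C change from baseline at steady state for PD, evaluated at
Cavg,ss = AUC_ss/24. Group means (arithmetic, matching "mean AUC" summaries;
a geometric option exists) and test/reference ratios are summarized across
iterations as the 50th (5th, 95th) percentiles. Groupings default to the
published bins: eGFR ≥90 / 60–<90 / 30–<60 mL/min and weight <70 / 70–100 /
>100 kg. Exact published ratio magnitudes depend on the joint covariate
distribution of the original studies, which is unavailable; the package's
tests therefore check the directions and the closed-form limit on
single-covariate populations, not the printed magnitudes.

## Known limitations

- No censored-likelihood handling of below-LLOQ data (exclusion only).
- Diagonal random-effect covariance; no inter-occasion variability.
- One residual term per fit in estimation.
- The metabolite is not modeled; the parent concentration is treated as the
  exposure surrogate throughout.
- Published objective-function values are not reproducible (different data,
  different software numerics); recovery and oracle checks take their place.
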