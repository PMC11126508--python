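# Methods

## Model

The package models a child's weight status as a continuous-time Markov
chain on four ordered states (underweight = 1, healthy weight = 2,
overweight = 3, obesity = 4). The generator Q is constrained to the six
adjacent transitions (1↔2, 2↔3, 3↔4): direct jumps such as healthy weight →
obesity have zero instantaneous rate, but acquire positive probability over
any finite interval through the intermediate state. The Markov assumption —
future movement depends only on the current state — is untestable from
panel data alone and inherited by everything downstream.

Panel observations are interval-censored: the state is known only at the
measurement ages, and the likelihood contribution of an interval is the
corresponding entry of P(Δt) = exp(Q·Δt). Exact decimal ages are used for
Δt, not nominal wave ages, because field work lags the nominal wave age by
a child-specific amount. Time-homogeneity is assumed only *within* an
adjacent wave pair; the base-case analysis fits a separate Q per pair and
links the five annual matrices piecewise. Scenario 1 fits a single Q to all
intervals anchored at the first wave; scenario 2 reuses the first pair's Q
for all of childhood.

Covariates act proportionally on intensities, q_rs(x) = q⁰_rs·exp(β_rs′x),
with transition-specific coefficients reported as hazard ratios. This
log-linear form is the standard proportional-intensities model and the only
one consistent with reporting per-transition HRs against a reference level.
Categorical covariates are dummy-coded with the lowest level as reference;
fits are univariable by default (one covariate at a time), and a
`merge_levels` utility exists for sparse levels whose fits cannot converge
— merging is always explicit, never automatic.

## Survey weighting and inference

Design weights multiply each child's whole log-likelihood contribution
(design-weighted pseudo-likelihood, the standard M-estimation form). Point
estimates are taken at the weighted optimum. Variances are **never** taken
from the weighted Hessian: they come from JKn delete-one-cluster jackknife
replication. Each replicate zeroes one cluster and rescales its stratum
mates by n_h/(n_h−1); the variance estimator is
v = Σ_h ((n_h−1)/n_h)·Σ_{j∈h}(θ̂_(hj) − θ̂)². Replicates are refit through
the full pipeline (warm-started from the full-sample optimum, which changes
nothing at the optimum), so CIs for annual probabilities reflect the
nonlinearity of the matrix exponential rather than a delta-method
linearisation. Intervals are normal-theory 95% on the log scale for
intensities and hazard ratios and on the identity scale clipped to [0, 1]
for probabilities. Replicate fits that fail to converge are dropped with
per-stratum renormalisation when at most 5% fail; beyond that the
inference errors out loudly, since silent bias is worse than an error.
Note the count-based n_h/(n_h−1) rescaling preserves stratum weight totals
exactly only when cluster weight totals within a stratum are equal.

## Growth reference and classification

BMI is standardised by the LMS method: z = ((y/M)^L − 1)/(L·S), or
log(y/M)/S when L = 0, with L, M, S linearly interpolated in age within
sex (monthly table granularity makes the interpolation method immaterial).
UK population-monitoring cut-offs place the boundaries at the 2nd, 85th and
95th centiles, computed from the normal quantile function rather than
hard-coded decimals (≤ 2nd underweight; < 85th healthy; < 95th overweight;
≥ 95th obesity). WHO cut-offs switch at 60 months: overweight is z > 2
(> 1 from 61 months) and obesity z > 3 (> 2 from 61 months). Records with
|z| > 5 are flagged implausible and excluded; the threshold is
configurable. The licensed UK90/WHO tables are not shipped: a synthetic LMS
table with realistic shapes (adiposity-rebound dip near age 5–6, adolescent
rise, negative L) supports tests and demos, and any user table in the same
CSV layout is accepted.

## Synthetic cohort generator

The simulator emulates the structure of a stratified, clustered UK birth
cohort: 9 strata and 398 clusters by default, with the last 3 strata
"disadvantaged" and oversampled at twice the base inclusion rate (weights
are the mean-normalised inverse inclusion probabilities); every cluster in
the roster receives at least one child so the realised sample spans the
design. Default conditions: 10,000 children; waves at nominal ages 3, 5, 7,
11, 14, 17; baseline state distribution (0.78, 72.70, 15.90, 10.63)% as in
the survey-weighted validation cohort; measurement ages equal to nominal
age plus a non-negative field-work delay (mean 0.13 y, SD 0.15 y, matching
a mean age of ~3.13 at the age-3 wave), rounded to 0.01 y; monotone
inter-wave dropout at 9% per wave, consistent with the observed shrinkage
of the pairwise datasets across waves; 5% covariate missingness; a sex
covariate with a default hazard ratio of 1.2 on healthy → overweight.
Generating intensities are piecewise in three bands — (3, 7): u→h 0.30,
h→u 0.003, h→o 0.035, o→h 0.25, o→ob 0.10, ob→o 0.12 per year; (7, 11):
0.08, 0.0015, 0.015, 0.03, 0.055, 0.017; (11, 18): 0.10, 0.0025, 0.018,
0.08, 0.055, 0.040 — chosen to echo the published age gradient: children
under 7 both acquire and resolve excess weight much faster than older
children. Paths are simulated exactly (exponential holding times, embedded
jump chain) through the band structure, so the generator and estimator
share one definition of the process and parameter recovery is meaningful.

What the simulator does not emulate: measurement error and state
misclassification, non-monotone (returning) missingness by default,
covariate-dependent attrition, secular/cohort trends, and within-cluster
correlation of weight trajectories beyond what the design induces. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated sampling design, not robustness to those
real-data features.

## Numerical choices

Optimisation is over unconstrained log-intensities and β by L-BFGS-B
(ftol 1e−12, gtol 1e−7, max 500 iterations) with a Nelder–Mead fallback
when the quasi-Newton line search stalls; non-finite optima are flagged
non-converged, and results objects refuse to emit derived quantities from
non-converged fits. Starting values are crude event-count/person-time
rates with zero-count transitions floored at 1e−6/yr to keep the optimiser
in the interior. Inside the likelihood, P(Δt) for all unique interval
lengths is computed from one eigendecomposition per covariate profile
(P(t) = V·diag(e^{λt})·V⁻¹), falling back to scipy's `expm` when the
eigenvector matrix has condition number above 1e8 or a non-negligible
imaginary part appears; agreement with the power-series oracle is at the
1e−8 level. Likelihood cells are aggregated over (covariate profile, Δt,
from, to), so replicate refits only re-aggregate weights. An observed
transition that is impossible under the current parameters returns −∞, not
an exception, so optimisers can recover.

Markov traces use annual cycles with no half-cycle correction (that
belongs to downstream cost-effectiveness use). When a trace horizon runs
one year past the last fitted band (age 17 → 18), the final band's annual
matrix is reused; the extension is logged. Validation-cohort expansion
replicates each child round(factor·w_i/mean(w)) times, rounding half away
from zero; the expanded head-count *distribution* is the meaningful
output, since exact published expansion totals are not reconcilable from
the stated procedure. Predicted-to-observed ratios with zero observed
prevalence are reported as undefined (NaN), never infinity.

## Design choices on genuinely open points

- Whether published covariate HRs come from univariable or mutually
  adjusted fits is unstated; both are supported, univariable is default.
- Scenario 1 treats gaps (e.g. waves at ages 3 and 17 only) as single long
  intervals, consistent with "at least one repeated measure".
- CI construction is replication-through-the-pipeline with normal theory
  on a transform-appropriate scale, the standard replicate-weight usage
  and the only one that produces the observed asymmetric intervals.
- Replicate execution is sequential regardless of any worker-count option
  so results can never depend on scheduling.

## Problem sizes used in the checks

The recovery study uses 5,000 children over 6 waves with 60 clusters in 6
strata and a true sex HR of 1.5 on healthy → overweight; the CI-coverage
study uses 200 reduced replicates (400 children, 3 waves, 24 clusters,
mixed baseline — a smaller design would leave the return rate
unidentified); the weighting-bias study uses 20,000 children over one
2-year interval with the full 398-cluster design and 3× oversampling of a
transition-prone subgroup, compared against exact expected-count
estimands. These sizes are the package's own trade-off between statistical
resolution and a test suite that runs in minutes.

## Known limitations

State misclassification (no hidden-Markov layer), time-inhomogeneity
*within* a band, exact-transition-time observations, Taylor-series
linearisation variance, bootstrap/BRR weights, and multiple imputation of
missing covariates are all out of scope; analyses are complete-case with
an explicit exclusion ledger. Estimates from intervals as wide as four
years (ages 7–11) average over any within-interval age dependence.
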