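# Methods

## Model and estimation

The core object is a discrete-time Markov chain on three states —
non-disabled (nd), disabled (dis), dead — with an elementary step of one
month (h = 1/12 year). The four transitions among living states and to death
are multinomial logits in age: for transient state *i* at age *x* years,
p_ij(x) = exp(a_ij + b_ij·x) / (1 + Σ_k exp(a_ik + b_ik·x)), with retention
p_ii taking the remaining mass and the dead row exactly absorbing. Age
enters each logit linearly; the age used for a step is the age at the step's
start, and participant ages live on the monthly clock (baseline ages rounded
to the month). A quadratic age term is deliberately out of scope.

Eight parameters are estimated per stratum (sex × exposure group). The data
are interval-censored: states are seen only at annual waves, deaths carry an
exact month, emigration right-censors. Likelihood contributions:

* a consecutive wave pair (state s at month t, s′ at t′) contributes the
  (s, s′) entry of the product of the monthly step matrices spanning the
  gap — unobserved intermediate states are integrated out by the matrix
  product, never imputed;
* a death at month m after a last wave in state s at t contributes
  Σ_l [Π_{u=t}^{m−2} P(x_u)]_{s,l} · p_{l,dead}(x_{m−1}), l ∈ {nd, dis}:
  alive in some living state at m−1, then the death step. Death months are
  taken at face value (registry transfer); if only an interval were known
  the death is treated as occurring in its recorded month — a documented
  approximation. The alternative (wave-interval censoring of deaths) is a
  straightforward variant but exact-month is the default and the only
  implemented path;
* emigration contributes nothing beyond the last wave;
* disability-certification events are carried in the dataset but do not
  enter the likelihood, which uses wave states and dated deaths only. In
  real registry data the wave states are themselves derived from
  certification records; here the annual wave is the unit of observation
  and the certification month is available for descriptive use.

Because an interval's likelihood depends only on (start age in months, gap
length, endpoint states), identical intervals are aggregated into cells with
multiplicities, and all cell products are evaluated with a handful of
batched matrix multiplications per likelihood call. Optimisation is
L-BFGS-B from the initial point (all intercepts −4, slopes 0), with logits
internally centred at age 80 purely for conditioning; results are reported
on the (intercept at age 0, slope per year) scale. Convergence: relative
log-likelihood change below ~1e−8 or gradient ∞-norm below 1e−6, at most
500 iterations. The covariance is the inverse of the numerically
differentiated observed information at the optimum (central-difference
Hessian), transformed back to the reporting scale.

A transition with no endpoint-observable support (no wave pair of that kind;
no death following that living state) cannot be identified and is pinned to
the sentinel intercept −50 (odds e⁻⁵⁰, structurally absent) with zero
variance. The pipeline requires at least 10 such observable transitions
before fitting one (`min_transitions`), a conservative small-cell policy for
sparse strata.

## Life-table quantities

Occupancy from index age x₀ = 65: M_t = Π_{u<t} P(x₀+u·h), M_0 = I. The
expected years in living state j before the closure age are the trapezoid
sum e_j = h·(½[M_0] + [M_1] + … + [M_{T−1}] + ½[M_T])_{nd,j}. DFLE = e_nd,
duration with disability = e_dis, TLE = e_nd + e_dis — exactly additive by
construction. Default conditioning starts the chain non-disabled at x₀ (the
entry cohort is disability-free by design); a prevalence-weighted variant
mixes the occupancy rows by a supplied initial distribution for
population-style expectancies.

Closure age x_max = 115 years: beyond any data support, survival there is
negligible under realistic hazards; a warning fires if survival at closure
exceeds 1e−4 (then truncation would be material — typically a symptom of a
poorly identified mortality slope in a tiny stratum). Non-monthly step sizes
are defined through matrix powers of the monthly matrix (fractional powers
for refinement), which keeps the chain consistent across step sizes; halving
h moves DFLE only through quadrature, by well under 0.02 years on the
default grid.

Confidence intervals are percentile parametric bootstrap: B = 1000 draws
(default) from N(θ̂, Σ̂), expectancies recomputed per draw (vectorised across
draws), 2.5th/97.5th percentiles. Percentile rather than normal-theory
intervals because DFLE is a nonlinear functional of θ. A covariance with
slightly negative eigenvalues (numerical Hessians) is repaired by clipping
at zero; a strongly indefinite one is refused. The bootstrap refuses
non-converged fits outright.

`microsim_expectancy` is an independent oracle for the same integrals: N
simulated lives stepped through the same matrices, time in state accumulated
with the identical trapezoid convention, Monte-Carlo standard errors from
the sample SD. Matrix products and microsimulation must agree within a few
SEs — this is a structural identity, not a statistical hope, and the test
suite enforces it across the full default parameter table.

## Synthetic cohort generator

The generator emulates the data structure the estimator assumes:

* entry cohort all non-disabled, aged ≥65 (ages truncated-normal per group,
  the latent location shifted so the *truncated* mean matches the published
  group mean; bounds [65, 100]);
* four exposure groups with published sex-specific sizes and published
  covariate marginals (BMI, smoking, walking, depression-screen prevalence,
  disease history); a participant assigned to group g receives exactly g
  activity categories with a non-"none" frequency, so coded exposure equals
  the assigned group;
* depression-screen items are constructed to realise the drawn depression
  flag (score uniform on {2..5} if flagged, {0,1} otherwise);
* latent monthly transitions per sex × group from true parameter tables;
  the defaults were calibrated by root-finding (`calibrate_intercepts`) so
  the model-implied DFLE and duration with disability at 65 match the
  published group gradient, with fixed Gompertz-like age slopes (0.10/yr for
  incidence and non-disabled mortality, 0.09/yr for disabled mortality,
  recovery declining at 0.02/yr) and a sex-specific excess disabled
  log-odds of death (+1.6 men, −0.4 women — men's short published duration
  with disability requires high disabled mortality, women's long duration
  low);
* annual observation waves at months 0, 12, …, 132 while alive and not
  emigrated (a wave coinciding with the emigration month is censored);
  death months recorded exactly; first entry into disability recorded as a
  certification event; emigration is independent monthly censoring with
  default probability 2.7e−4, calibrated so ≈3.1% of the default cohort
  emigrates within follow-up;
* covariates other than sex/group/age do not enter the true hazards by
  default (they exist to exercise stratification plumbing); a `params_hook`
  lets tests inject covariate-dependent hazards to probe confounding.

What the generator does **not** emulate: the real joint covariate
distribution beyond the published marginals, certification lag (the
certification date equals the first disabled month), household or
geographic clustering, informative censoring, and any dependence of
questionnaire missingness on health. Passing tests therefore demonstrate
correctness of the estimation and life-table machinery under the model's
own assumptions — not robustness to their violation in real registry data.

## Numerical choices and degenerate inputs

* Log-sum-exp stabilisation in every logit evaluation; step-matrix rows sum
  to one within 1e−12.
* A likelihood evaluation returning a zero-probability observed path yields
  −∞ (the optimiser backtracks); an observation after death is a validation
  error at dataset construction.
* Ties at the outcome horizon resolve death > emigration > disabled >
  non-disabled.
* Percentages and years are rounded (one decimal) at display only; all
  internal values keep full precision.
* Empty subgroups yield table cells marked unavailable; the run continues.
* Determinism: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; a full study rerun with the same config is
  byte-identical (cell-level bootstrap seeds are derived from the config
  seed with a stable hash).

## Design decisions that were genuinely open

* The depression screen is scored exactly as printed (items 1, 2, 4 score 1
  for "yes"; items 3 and 5 score 1 for "no"), although the direction of the
  positively-worded items may look counterintuitive; scoring is centralised
  in one table should a user need to override it.
* Participants with missing covariates stay in the main analysis and drop
  only from a stratified run whose stratifier is missing; missing any of
  the three activity items makes exposure missing (the conservative
  reading).
* Whether published expectancy tables report status-conditional or
  implied-prevalence-weighted quantities is not stated in the tradition
  this design follows; status-conditional (non-disabled at 65) is the
  default here, matching the disability-free entry cohort, and the
  prevalence-weighted variant is exposed.
* The variance method behind the original software's CIs is not published;
  the percentile parametric bootstrap is this package's choice, and CI
  widths are validated only by coverage on synthetic truth (95% nominal,
  observed within [88%, 100%] over replicate cohorts).

## Problem sizes used in the validation studies

Simulation studies in the test suite use: 200 replicate cohorts of n=10,000
(132 months, monthly steps) for parameter-level Wald coverage; 50 cohorts
with B=300 bootstrap draws for DFLE interval coverage; 100,000 simulated
lives per parameter set for the microsimulation oracle; and three replicate
cohorts of 40,000 (20,000 per sex, balanced groups, a common age profile of
73.6 (6.0) years across groups so that only the hazards differ) for
recovery of the graded group effect, whose true DFLE gradient spans the
published ≈5-year endpoint gap with evenly spaced intermediate groups
(adjacent near-ties would not be resolvable at this sample size and are not
part of the claim under test; group-specific age profiles would likewise
add extrapolation variance unrelated to the gradient being recovered).

## Known limitations

* Linear-in-age logits cannot bend late-life hazard trajectories; severe
  misspecification shows up as material survival at closure (warned).
* The likelihood assumes non-informative censoring (emigration independent
  of health), as does the generator.
* No covariate-adjusted transition model: stratification is the only
  confounding control, mirroring the analysis design this package
  replicates.
* Wave states between observations are integrated over, not recovered; the
  method cannot date disability onset more finely than the model implies.
* The bootstrap propagates parameter uncertainty only; it does not reflect
  model-selection or misspecification uncertainty.
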