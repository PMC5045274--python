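# Methods

## The generating law

Each individual has covariates drawn independently (by default) from the
published marginals: continuous predictors Normal(mean, sd²) in natural units,
binary predictors Bernoulli(prevalence). The hazard is constant in time,

    λ_i = exp(b + Σ_j β_j x_ij),

so event times are exponential and proportional hazards holds exactly.
Censoring is administrative: C_i ~ Uniform(0, H) with horizon H = 10 time
units. Observed time is min(T_i, C_i), with an event when T_i ≤ C_i. No
survival-time family or follow-up horizon is published for the source data;
the exponential/uniform pair is the simplest law satisfying the proportional
hazards assumption exactly, and the horizon only matters through the
calibrated baseline, so these are module defaults rather than data facts.

The twelve predictors, their distributions, and their generating log hazard
ratios come from the published covariate summary and fitted-model tables: BMI
(26.25 ± 4.41, β = 0.0233), age (48.66 ± 14.09, β = 0.0725), sex (prevalence
0.51, β = 0.4667), RATIO (4.04 ± 1.31, β = 0.0410), SBP (131.84 ± 20.34,
β = 0.0069), then binary HYPER (0.05, 0.2278), TYPE2 (0.02, 0.5174), SMK
(0.28, 0.3964), FHCVD (0.04, 0.8959), BRA (0.01, 0.2991), BAF (0.01, 0.5293),
RENAL (0.004, 0.4919). Two deliberate choices:

* **Smoking** is dichotomised before generation (light + moderate + heavy =
  0.07 + 0.11 + 0.10 = 0.28), matching the single published smoking
  coefficient.
* **Renal disease** prints as prevalence "0.00" after rounding; 0.004 is used —
  strictly positive, below the 0.005 rounding boundary, preserving the
  "extremely low prevalence" behaviour that drives monotone likelihood.

### Baseline calibration

The marginal event rate is fixed at 4.5%. For a fixed pilot draw, individual
i becomes an event iff `log E_i − log C_i − Σβ_j x_ij ≤ b` (E_i the unit
exponential), so the simulated rate is a monotone step function of the
baseline b and bisection on it is deterministic given the seed. The default
pilot (n = 200,000) makes the Monte-Carlo SE of the rate ≈ 0.0005, well under
the default tolerance 0.002. A fresh 200k confirmation cohort lands within
±0.2 percentage points of 4.5%.

### Correlation and external validation

The source data's covariate correlations are unpublished; the default is
independence, with an optional latent-Gaussian correlation (marginals
preserved by thresholding at the prevalence quantile). This is the single
largest declared source of discrepancy from the original study: under
independence, the full conditional hazard ratio of a predictor is also its
marginal association. For the EPV = 2 three-predictor cells that matters
concretely — the probability that all six sampled events share one sex level
(the monotone-likelihood trigger) is ≈ 6% here versus ≈ 3% in the source
data, where correlation and confounding attenuate the marginal sex-event
association. Convergence counts at very low EPV are therefore reproduced
only up to this gap (and up to the nonconvergence rule below).

The validation cohort is drawn from the same law on a disjoint random
stream. The original study validated on a geographically separate
subpopulation whose covariate shift is unpublished; a shift hook
(per-variable mean/prevalence deltas) exists but defaults to off, so
external-validation degradation is only qualitatively comparable.

## The Cox fitter

Newton–Raphson from β = 0 on the Breslow-ties partial likelihood (resampling
with replacement duplicates rows, so tied times are routine; Efron weights
are available behind a config flag and agree with Breslow on tie-free data).
Score and information use suffix sums over the time-ordered risk sets; the
information is assembled from a single weighted Gram matrix via
Σ_e S₂(t_e)/S₀(t_e) = Σ_j w_j x_j x_jᵀ A_j with A_j the cumulative sum of
1/S₀ over events at risk-set entry, which keeps the cost at O(np²) per
iteration without materialising n × p × p arrays. Step-halving is applied
whenever a Newton step would decrease the likelihood.

**Nonconvergence rule.** The original analyses treated "error message from
the partial-likelihood maximiser" as nonconvergence, which is
software-specific. Here the rule is deterministic and documented:

* converged ⇔ max |step| < 1e-9 within 50 iterations, all |β̂_j| < 15, and
  invertible observed information;
* monotone likelihood flagged when any coefficient path exits |β| = 15
  (under monotone likelihood the divergent coordinate grows roughly linearly
  per iteration, so the bound is reached long before the iteration cap);
* nonconvergent fits report NaN standard errors and are excluded from all
  aggregates, never redrawn.

The bound 15 on the log-hazard scale corresponds to hazard ratios beyond
e¹⁵ ≈ 3×10⁶, far outside any plausible estimate at these sample sizes.
Verified against independent implementations: coefficients, standard errors
and log-likelihood agree with statsmodels PHReg (Breslow) to ~1e-6 on tied
data, with lifelines on tie-free data, and with dense grid-search /
Nelder-Mead maximisation of an independently coded partial likelihood on
small fixtures.

## Resampling design

For a model with p parameters at a given EPV, each replicate draws exactly
`n_events = round(EPV·p)` rows from the event stratum and
`round(n_events(1−r)/r)` from the non-event stratum (r = 0.045), both with
replacement — e.g. EPV 2 with 3 predictors gives 6 events + 127 non-events.
Rounding is to the nearest integer (the original design does not state the
rounding rule). Each replicate runs on its own spawned RNG substream, so
results are bitwise reproducible and independent of execution order.

"True" coefficients for bias/coverage are the generating values — in this
synthetic setting the full-data estimand coincides with them up to vanishing
error, and exactness improves testability; a full-data-refit truth mode is
available (`run_on_user_cohort` uses it by default when no truths are
given). "True" performance values are the generating model's prognostic
index evaluated on a large fresh reference cohort.

The default development cohort is 200,000 individuals (~9,000 events) rather
than the original ~2M: the resampling cells see the development data only
through its two strata, and at 200k the stratum-resampling error is
negligible relative to replicate noise. Both sizes are configurable.

## Metrics

* **Percent relative bias** `100(mean(β̂)−β)/β`, over converged replicates.
* **Variance ratio** `mean(s²)/var(β̂)` with the across-replicate sample
  variance (ddof 1) as the empirical variance. The originally printed
  empirical-variance formula is internally inconsistent (constant in the
  replicate index); the across-replicate dispersion of the estimates is the
  quantity the underlying methodology defines, and is what is implemented.
* **Coverage**: fraction of replicates with |β̂−β| ≤ 1.959964·s.
* **c-index**: Harrell conventions — usable pairs are those orderable under
  censoring (strictly earlier event, or event tied in time with a censored
  subject); prognostic-index ties score ½; tied event times are unusable.
  Checked against exhaustive pair enumeration and lifelines.
* **D-statistic**: PI replaced by Blom normal scores
  Φ⁻¹((i−3/8)/(n+1/4)) averaged within PI ties, scaled by 1/κ, κ = √(8/π);
  D is the coefficient of a univariate Cox fit on the scaled scores.
  Constant PI gives D = 0 by convention. For PI ~ N(0, σ²) generating the
  hazard at unit coefficient, D ≈ κσ (verified by simulation). The source
  study does not print the estimator's internals; this follows the cited
  construction.
* **R²** measures: `R²_D = (D²/κ²)/(π²/6 + D²/κ²)` and
  `R²_OXS = 1 − exp(−2(l_β−l₀)/k)`. The latter is monotone decreasing in k
  at fixed likelihood gain; the verbal claim that it grows with events holds
  when the gain grows proportionally, and only the algebraic form is
  asserted here.
* **Calibration slope**: coefficient of a univariate Cox refit of validation
  survival on the development model's PI; < 1 flags overfitting. On
  external evaluation, `R²_OXS` uses the validation partial likelihood at
  the fixed development coefficients versus the null.

## Variable selection

Backward elimination drops one variable per step — the largest Wald p-value
above the threshold, ties broken toward the later list position — and stops
when all retained p ≤ threshold or none remain. The "AIC" criterion is the
exact single-degree-of-freedom correspondence ΔAIC < 0 ⇔ p > 0.1573 applied
to the same single-drop scheme. The EPV denominator counts all 15 candidate
parameters (5 real + 10 noise), since EPV is defined against candidate
predictors. Fresh noise columns and fresh resamples are drawn per replicate
(whether the original study reused fixed-model samples is unstated). A
nonconvergent fit at any elimination step marks the replicate nonconvergent.

## Problem sizes and numerical defaults

Analysis drivers default to desk-scale runs (250 replicates per grid cell,
150 for selection, 100 with performance metrics, 20k validation) chosen so
each script completes in minutes on one CPU; every count is a flag, and 1000
replicates reproduces the original design. Tolerances: Newton step 1e-9;
calibration 0.002; bisection bracket expansion capped at 60 doublings.
Ridge stabilisation is available (`ridge_eps`) but defaults to 0 — no
penalisation, matching the practice under study.

## What passing tests do and do not show

The generator reproduces marginal distributions, the event rate, the
proportional-hazards structure, and the published coefficient vector — not
covariate correlations, practice-level clustering, registration windows,
missing data, or real baseline-hazard shape. Agreement on the qualitative
laws (nonconvergence driven by low-prevalence binaries, bias/variance-ratio/
coverage improving in EPV, overfitting dissipating in the calibration slope,
AIC-criterion superiority for retaining true predictors) is evidence about
the method, not a validation against the proprietary source records; exact
cell counts at very low EPV depend on the unpublished correlation structure
and the nonconvergence operationalisation, as noted above.
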