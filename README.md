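# epvsim

Monte-Carlo machinery for studying **events-per-variable (EPV)** requirements of
Cox proportional-hazards prediction models, in the presence of low-prevalence
binary predictors and automated variable selection.

## Who this is for

Biostatisticians and epidemiologists who want to know how many outcome events a
survival prediction model really needs. The widely used rule of thumb — ten
events per candidate parameter — was derived under narrow conditions. This
package lets you interrogate that rule under a realistic cardiovascular-risk
generating law (or your own cohort): how often does the partial-likelihood
maximiser fail outright (monotone likelihood), how biased are the coefficients,
do the model-based standard errors match the true sampling variability, and how
does predictive performance on external data degrade at low EPV?

## What it does

1. **Synthetic cohort generator** (`epvsim.cohort`) — builds a 12-predictor
   survival cohort from published summary statistics alone: four continuous
   covariates (BMI, age, SBP, cholesterol ratio ≡ RATIO), and eight binary ones
   down to prevalence 0.004 (renal disease). Event times are exponential with
   hazard `exp(b + Σ βⱼxⱼ)`; censoring is administrative-uniform; the baseline
   `b` is calibrated by bisection so the marginal event rate is 4.5%.
2. **Cox fitter** (`epvsim.cox`) — Newton–Raphson maximisation of the
   Breslow-ties partial likelihood with step-halving, Wald inference, and a
   deterministic nonconvergence rule: a fit converges only if the step
   criterion is met within 50 iterations, every |β̂ⱼ| < 15, and the observed
   information is invertible; a coefficient exiting the bound flags monotone
   likelihood (the survival analogue of separation).
3. **Resampling engine** (`epvsim.resampling`) — draws replicates with
   replacement, stratified so each sample has *exactly*
   `round(EPV × p)` events and the 4.5% event fraction; fits the nested
   3/5/7/10/12-predictor models; excludes nonconvergent fits without
   replacement.
4. **Metrics** (`epvsim.metrics`) — signed percent relative bias
   `100(β̄̂−β)/β`, model-to-empirical variance ratio `mean(s²)/var(β̂)`, 95%
   coverage, Harrell's c-index, the Royston–Sauerbrei D-statistic (Blom
   normal scores of the prognostic index scaled by κ = √(8/π), refit in a
   univariate Cox model), `R²_D = (D²/κ²)/(π²/6 + D²/κ²)`, explained
   randomness `R²_OXS = 1 − exp(−2(l_β − l₀)/k)`, calibration slope, RMSE.
5. **Selection study** (`epvsim.selection`) — the 5-predictor model plus 10
   N(0,1) noise variables, backward elimination at p < 0.05 or p < 0.157 (the
   exact 1-df AIC rule), retention frequencies per variable and for "all five
   real predictors simultaneously".
6. **Orchestration** (`epvsim.study`, `epvsim.cli`, `analysis/`) — config-driven
   full-grid runs, delimited report tables, and a user-cohort entry point for
   applying the pipeline to your own `time,event,covariates` CSV.

## Worked example

```bash
python analysis/01_calibrate_generator.py --seed 1
```

prints (abridged):

```
baseline log hazard (calibrated): -10.8398
marginal event rate on fresh n=200,000 cohort: 4.58% (target 4.50%), 9,162 events
variable       kind  target  observed  ...
     BMI continuous  26.250    26.245
     ...
   RENAL     binary   0.004    0.0040
```

i.e. the calibrated generator hits the target event rate and every covariate
marginal. Then

```bash
python analysis/02_fixed_model_grid.py --seed 1 --replicates 250
```

```
converged fits per cell (rows: model size, cols: EPV):
epv         2.0   5.0   10.0  15.0  20.0  25.0  50.0
3            233   250   250   250   250   250   250
5            245   250   250   250   250   250   250
7             52   155   219   238   244   249   250
10            17    99   174   208   239   240   250
12             0    30   101   179   199   230   249
```

Nonconvergence is driven far more by the low-prevalence binary predictors
(models 7–12) than by EPV itself, and vanishes as EPV grows — the central
qualitative finding. `analysis/03_predictive_performance.py` shows the
external calibration slope of the 12-predictor model rising from 0.80 at
EPV = 5 to 0.97 at EPV = 25 (overfitting dissipating), and
`analysis/04_variable_selection.py` shows the AIC-style criterion retaining
all five real predictors about twice as often as the 0.05 criterion while
keeping each noise variable at roughly its nominal level.

## Layout

```
src/epvsim/        library (generator, fitter, resampling, metrics, selection, study, CLI)
analysis/          numbered narrative drivers writing tables under results/
tests/             pytest suite (unit, property, end-to-end)
scripts/           acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
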