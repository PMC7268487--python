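# Methods

This note documents the statistical content of the package: the models and
procedures, their assumptions, the tunable parameters, what the synthetic
generator does and does not emulate, and the numerical and design choices
made where the method description leaves room.

## The two-level classification

**Income types (first level).** Countries are assigned to four World Bank
income bands on per-capita income in current USD, with inclusive upper
bounds: type I ≤ 1,025 < II ≤ 3,995 < III ≤ 12,375 < IV. GDP per capita
stands in for GNI per capita, to which it is roughly equivalent at this
resolution. The thresholds are a configurable `IncomeThresholds` value;
defaults are the 2018 operational thresholds. A packaged listing maps the
176 countries of the 2015 reference analysis to their types (26/50/51/49
per type). One lower-middle-income entry of that listing (Eswatini) is a
synthetic completion of an incomplete source table and is flagged as such in
`fixtures.SYNTHETIC_TABLE1_ENTRIES`.

**Development stages (second level).** Each stage indicator — neonatal
mortality per 1,000 live births (medical development) and urbanization rate
in % (social development) — is discretized into k = 6 strata by Fisher–Jenks
natural breaks: the exact dynamic-programming optimum of the within-class
sum of squares, computed over the unique values weighted by multiplicity so
tied observations always share a class. Breaks are computed once on the full
base-year cross-section (globally, not within income branches: the two-level
tree reads more coherently when a given stratum means the same thing on
every branch). Class labels are monotone in the value, so the stored break
points re-classify new (e.g. projected) values deterministically.

The composite stage is a weighted mean of the two strata, where the neonatal
stratum is first reverse-oriented (oriented = 7 − stratum) so that a higher
stratum always means *more developed* for both indicators — without a fixed
orientation the composite would be meaningless. The weights are the
normalized Geodetector q-values of the two indicators against the NCD
response (see below), and the weighted mean is rounded half-up to an integer
1..6 and clamped. Round-half-up of the weighted stratum mean is the simplest
map onto six ordinal stages; it is monotone non-decreasing in each oriented
stratum, which is the property the stage ordering relies on.

## Geodetector q-statistic

For response values y partitioned by a categorical stratification into L
strata of sizes N_h,

    q = 1 − (Σ_h N_h σ²_h) / (N σ²) = 1 − SSW/SST ∈ [0, 1],

with population variances (denominator N) in both numerator and denominator,
so the variance convention cancels and q is exactly one minus the
within-to-total sum-of-squares ratio. q = 0 iff all stratum means are equal;
q = 1 iff y is constant within every stratum. q is invariant under affine
transforms of y and under stratum relabeling, and can only grow under
refinement of the stratification.

Significance is assessed by a Monte-Carlo permutation test on the stratum
labels with p = (1 + #{q* ≥ q}) / (1 + B), default B = 999, seeded. The
published tables report p-values without naming a test; a permutation null
is assumption-free and exactly reproducible. (The noncentral-F approximation
from the Geodetector literature is deliberately not used.) Missing responses
are dropped pairwise with a logged count before computing q.

Weight allocation normalizes the per-factor q-values to proportions,
w_f = q_f / Σq; weights are kept at full precision and rounded only for
display. The published q-values for the two NCD indexes are shipped as
reference constants (`fixtures.REFERENCE_Q`); they derive from an
unpublished WHO/World Bank extract and cannot be recomputed here, but
normalizing them reproduces the published stage weights (0.55/0.45 and
0.75/0.25) exactly at the printed precision.

## Cross-classified multilevel model

With income type t and development stage s as crossed (non-nested) grouping
factors,

    y_i(t,s) = β₀ + β′x_i + u_t + u_s + e_i(t,s),
    u_t ~ N(0, σ²_u(t)), u_s ~ N(0, σ²_u(s)), e ~ N(0, σ²_e), all independent.

Default covariates x are the three forecastable development indicators: log
GDP per capita, urbanization rate, neonatal mortality. GDP enters on the log
scale because income effects on mortality are multiplicative in income; the
covariate list is configurable through `CrossClassifiedSpec` and recorded in
the fit.

**Estimation.** REML rather than ML: with only 4 and 6 group levels, ML
variance components are badly biased downward. Writing γ_f = σ²_f/σ²_e and
W = I + Σ_f γ_f Z_f Z_f′, σ²_e profiles out analytically and the REML
criterion is maximized over (log γ_t, log γ_s) — non-negativity holds by
construction, and γ values below e⁻²⁰ are snapped to an exact zero
(boundary) solution. The optimizer is Nelder–Mead from three fixed starts
(log γ = −4, 0, 2 on both axes), keeping the best criterion, which makes the
fit deterministic given the data; the returned object records the criterion
at each start. All linear algebra runs through the Woodbury identity on the
q = 10 columns of Z, so a criterion evaluation costs O(q³) independent of
the number of countries.

Fixed effects are GLS at the optimum with cov(β̂) = σ̂²_e (X′W⁻¹X)⁻¹; Wald
confidence intervals use the normal quantile. Random effects are predicted
by their BLUPs û_f = γ_f Z_f′ W⁻¹(y − Xβ̂), which shrink group means toward
zero. Prediction for a new observation adds the BLUPs of its groups; a group
level unseen in training contributes its prior mean 0 (population-level
prediction) with a logged notice.

**Weak identification.** With 4 and 6 levels the variance components are
intrinsically imprecise. Rather than failing, the results object exposes
`profile_interval(component)`: the profile-REML support interval at a given
level (default 95%, χ²₁ calibration), computed by re-profiling the other
component on a log-scale grid. A lower end of 0 means the component is
compatible with absence. The summary flags this whenever a factor has ≤ 6
levels.

**Baseline and hold-out.** The global baseline is OLS with the same
covariates (statsmodels), no group effects. `holdout_evaluate` draws a
random 70/30 split stratified by income type (so no branch empties; plain
random splitting occasionally loses a whole factor level), fits both models
on the training 70%, and scores the hold-out by R². Because the published
comparison is described as a plot of predicted against observed values, R²
is defined as the squared Pearson correlation; 1 − SSE/SST is computed and
reported alongside. The split is seeded and re-drawn (bounded) if a factor
would lose all its training levels.

## Synthetic data generator

The generator is the package's test bed: it produces cross-sections with
exactly the structure the analysis assumes.

* GDP per capita: log-normal, log-mean 8.3 and log-SD 1.4 — a right-skewed
  income distribution whose mass spans all four bands (roughly 16/34/29/21%
  of countries in types I–IV).
* Urbanization: logistic in log GDP, centered at log-GDP 8.3 with slope 0.9,
  plus N(0, 6²) noise, clipped to [0, 100] — urbanization saturates at both
  income extremes.
* Neonatal mortality: linear in log GDP (intercept 95, slope −9), plus
  N(0, 2²) noise, clipped at 0 — declines from ~33 at $1,000 to ~2 at
  $30,000 per capita.
* Outcomes: y = β₀ + β′x + u_t + u_s + e with Gaussian group effects and
  residual. The primary index (mortality rate) defaults to β₀ = 840,
  β = (−35, −1.2, 3), σ_type = 30, σ_stage = 20, σ_resid = 10 — a mean
  near 550 per 100,000 falling with development, with crossed heterogeneity
  dominating the residual. The death share uses its own effect structure
  (β₀ = −21, β = (8, 0.25, −0.3), SDs 3/2/1.5 on the percentage scale,
  clipped to [0, 100]) and *rises* with development, mirroring the two
  opposite published gradients.
* Group memberships are assigned by the pipeline's own classifiers applied
  to the simulated covariates (income thresholds; natural breaks; weighted
  composite stage), so synthetic data exercises the classification → model
  chain end-to-end. Because the pipeline's stage weights are derived from
  the outcome — which does not exist yet when the generator needs stage
  memberships — the generator uses fixed stage weights (0.55/0.45 for the
  mortality index, 0.75/0.25 for the share index, i.e. the published
  values); the analysis still re-derives its weights from q downstream.
* Histories: per-country neonatal series 1960–2016 as intercept +
  slope·year + N(0, 0.5²), slope drawn uniform in [−0.8, −0.1] (medical
  development only improves), anchored at the country's base-year value,
  clipped at 0. True (intercept, slope) lines are stored for oracle checks.

What the generator does **not** emulate: real country names or geography,
spatial correlation between neighbours, measurement error in the covariates,
non-Gaussian outcome tails, temporal nonlinearity in the histories, and any
dependence between the two outcome indexes beyond their shared covariates.
Passing tests therefore demonstrate correctness of the machinery and
calibration *under the model's own assumptions*, not the real-world validity
of the published estimates — the original WHO/World Bank/SSP extract is not
redistributable, so the published q-values, R² pair (0.30/0.11, 0.79/0.70 in
the reference analysis) and 2030 headline means are reference context, not
reproduction targets.

## Forecasting

The target-year scenario takes GDP and urbanization from a user-supplied
projection table and neonatal mortality from a per-country OLS line through
the 1960–2016 history evaluated at the target year, clamped at 0 from below
(negative mortality is meaningless; a history that would cross zero before
the target year forecasts 0). Countries missing projections or with fewer
than two history points are excluded with a logged notice, and each field
carries a provenance tag.

Re-classification at the target year reuses the break points, weights and
thresholds learned at the base year — re-running natural breaks on projected
values would silently change what "stage 4" means between years. Predictions
are fixed part + BLUPs of the assigned groups; death-share predictions are
clipped into [0, 100] with a logged warning (the Gaussian model is
unbounded), mortality-rate predictions at 0. The global summary is the
unweighted mean over countries by default, or population-weighted when a
population column is supplied; both conventions are defensible for a
"global average" and the choice is recorded in the summary object.

## Numerical choices and degenerate inputs

* q-statistic: constant response (SST = 0) is an error, not q = 0; SSW is
  clipped into [0, SST] against rounding; permuted q values are compared
  with a 1e-12 tolerance so exact ties count as exceedances.
* Natural breaks: requires at least k distinct values; DP ties break toward
  the earliest split, making the result deterministic; `gvf` is clipped into
  [0, 1].
* REML: log-γ search box [−20, 12]; Nelder–Mead tolerances xatol 1e-5 /
  fatol 1e-7 (criterion differences below ~1e-5 of a variance unit are
  statistically meaningless here); singular fixed-effect designs and factors
  with < 2 observed levels are rejected at model construction.
* Hold-out: train_fraction must lie strictly in (0, 1); the stratified draw
  retries at most 20 times before raising.
* Income classification requires strictly positive income; zero/negative
  values are data errors, not a band.
* Problem sizes in the tests and the acceptance script (n = 600 panels, 200
  recovery replicates, 100 hold-out replicates, 500 fuzzed oracle cases)
  were chosen so that Monte-Carlo standard errors sit well inside the
  asserted tolerances while the whole suite stays interactive on a single
  core.

## Known limitations

* The two-level tree discretizes continuous development; countries near
  break points can change stage under small covariate perturbations (the
  classification is exactly optimal, but not stable at the boundaries).
* Variance components at 4 and 6 levels carry wide profile intervals; point
  estimates should not be over-interpreted, and the Wald intervals for β
  ignore variance-component uncertainty (their simulated coverage at the
  study scale is nonetheless within [90%, 99%]).
* Forecasts are point predictions: no propagation of parameter or scenario
  uncertainty.
* Linear extrapolation of neonatal mortality over 14 years ignores the
  floor effects visible in rich countries; the 0-clamp is a crude guard.
* The permutation p-value resolution is 1/(B+1); with B = 999 the smallest
  attainable p is 0.001, which is why published "0.000" values appear here
  as p ≤ 0.001.
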