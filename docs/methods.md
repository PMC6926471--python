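# Methods

`lifegap` estimates life expectancy at birth (e0) for subcity units from
tabulated death and population counts, quantifies within-city inequality in
e0, and relates it to area-level socioeconomic status (SES). This note
documents the statistical procedures, the defaults and why, the synthetic
data the test suite runs on, and known limitations.

## Pipeline overview

1. **Ingest** — tidy CSVs of deaths and population by unit × sex × 5-year
   age group (0–4 … 70–74, 75+) × year, plus unit attributes (education,
   water, overcrowding, built-up fraction, centroid, city membership).
2. **Completeness** — per unit × sex, death-registration completeness by two
   death-distribution methods (GGB, SEG); harmonic-mean combination,
   truncation at 1, and inflation of death counts by 1/coverage.
3. **Smoothing** — Bayesian Poisson model per city × sex with AR(1)
   unit × age random effects; 2000 retained posterior draws of the
   unit × age rate surface.
4. **Life tables** — per draw: Gompertz extension past the 75+ open
   interval, abridged life table, e0 (and e40/e60); unit estimate = median
   over draws.
5. **Inequality** — population-weighted P90–P10 gap, Gini and CV per city ×
   sex; ICC of units nested in cities from a REML random-intercept model.
6. **Association** — within each city, WLS of unit life expectancy on SES
   scaled to its weighted P90–P10 range, adjusted for built-up fraction
   (optionally a quadratic polynomial in centroid coordinates); the model
   is refit on each posterior draw and the coefficients are pooled with
   Rubin's rules.

Sensitivity analyses are configuration switches of the same pipeline:
restrict to strata with coverage ≥ 0.9 without correcting; correct without
truncating at 1; use e40/e60 as the outcome; swap the SES proxy; add the
spatial polynomial.

## Death-distribution methods

Both methods compare the age distribution of registered deaths with
population change between two time points (the first and last years of the
population series — annual series stand in for two censuses) under
stable-population assumptions.

**GGB.** For each cutoff age a, the entry rate b(a) (persons turning a per
year, estimated from the geometric mean of the two profiles' exact-age
densities, relative to mid-period person-years above a), minus the growth
rate r(a+), equals the true death rate above a. Regressing b(a) − r(a+) on
the registered death rate d(a+) yields completeness = 1/slope; the intercept
estimates relative census-coverage change. The line is fit by orthogonal
(total least squares) regression — the convention in the
death-distribution literature, since both axes carry error — with OLS
available by flag.

**SEG.** The population at each exact age is reconstructed from registered
deaths above that age, projecting each death back by the age-specific
growth rate: N̂(a) = N̂(a+5)·exp(5·r) + D·exp(2.5·r). The open interval is
seeded with N̂(A) = D(A+)·(exp(r·e_A) − (r·e_A)²/6), where e_A is remaining
life expectancy at the open age under a Gompertz hazard fitted to the
observed 45–70 crude rates. Completeness is the arithmetic mean (median by
flag) of reconstructed/observed group populations over the fit range.

**Defaults.** Fit range: cutoff ages 15–65, avoiding child-mortality and
open-interval distortions. SEG runs unadjusted (δ = 0); a GGB-intercept
adjustment is available by flag. Truncation at 1 is applied to the combined
harmonic mean only; the per-method estimates are kept raw in diagnostics.
Units where a method fails (non-positive slope, zero deaths) inherit their
pooled city × sex estimate, flagged `pooled_fallback`. Completeness
estimation per unit × sex is the default (sexes are never pooled
downstream, so pooling them here would leak information across strata).

## Mortality smoothing

For one city × sex, with deaths D_ua and person-years E_ua summed over the
year window:

    D_ua ~ Poisson(E_ua · exp(α_a + θ_ua))
    θ_u,1 ~ N(0, σ²/(1−ρ²)),  θ_ua = ρ·θ_u,a−1 + N(0, σ²)

Priors: α_a ~ N(0, 10²), σ ~ Half-Normal(1), ρ ~ Uniform(−1, 1) — proper
and weakly informative on the log-rate scale. The AR(1) is stationary
("first-order autoregressive" is read as stationary rather than a random
walk); its mean-zero constraint is what identifies α_a as the city age
curve. Corrected death counts are real-valued; they enter the likelihood
through the gamma-function generalisation of the Poisson log-pmf, whose
count-dependent term cancels from every Metropolis ratio (stochastic
rounding is available as a config alternative).

**Sampler.** A vectorised Metropolis-within-Gibbs scheme:

- θ field: random-walk proposals on an even/odd age checkerboard — given
  one colour, cells of the other colour are conditionally independent
  across units and ages, so acceptance is evaluated cell-wise in one array
  operation;
- α_a: independence proposals from the Laplace approximation of the
  conditional (mode log((ΣD+½)/Σ E·e^θ), variance 1/(ΣD+½)), giving
  near-unit acceptance;
- ridge moves: the likelihood only constrains α_a + θ_ua, so translation
  proposals shift α_a against the θ column (per age, even/odd split) and a
  global scalar shift moves the whole α curve against the θ field. These
  are accepted on the prior ratio alone and remove the slow mode along the
  level ridge;
- σ (log random walk) and ρ (reflected random walk) on the AR(1)
  likelihood of θ.

Proposal scales adapt every 50 burn-in iterations toward ~0.35 acceptance
and are frozen afterwards. Chains are seeded from spawned `SeedSequence`
children. Split-chain R̂ and ESS (arviz) are computed on α, ρ, σ; a run
with R̂ > 1.05 on α or σ logs a warning and sets `converged=False` — never
a silent success. Retained draws are evenly thinned across the pooled
post-burn-in iterations (default schedule 5000 burn-in + 20 000 sampling,
2000 draws, 2 chains). Reduced schedules used in tests and the acceptance
script (e.g. 500/2000 × 2 chains on 20 units × 16 age groups) pass the same
convergence gates; problem sizes are chosen so the full suite runs in a few
minutes.

## Life tables

Rates are extended beyond the 75+ open interval with a Gompertz hazard
m(x) = A·exp(B·x) fitted by OLS of log rate on group midpoint over the age
groups 45–49 … 70–74 (midpoints 47.5–72.5). Groups 75–79 … 100–104 take the
prediction at their midpoints; the open 105+ group at 107.5. Extending to
105+ rather than leaving 85+ open changes e0 by < 0.05 years but avoids an
open interval carrying non-negligible survivorship.

The abridged life table uses q = n·m/(1 + (n − a)·m) with a = n/2 in closed
groups; the open interval takes q = 1 and L = l/m. The first group (0–4)
uses a₀ = 1.0 by default: deaths under 5 cluster in infancy, so the mean
time lived by those dying sits well below the 2.5-year midpoint. a₀ is a
parameter of every public entry point; the choice moves e0 by roughly
d₀·(2.5 − a₀)/l₀ (~0.02 years at low infant mortality). With the 0 and 1–4
groups merged in the input data, no within-interval split is attempted.

Per-unit life expectancy is the median over the 2000 per-draw e0 values;
the central 95% of draws gives the credible interval. The draw pipeline is
vectorised over (draw, unit) so 2000 × n_units schedules are one array pass.

## Inequality metrics

Weighted quantiles place each unit at the midpoint of its cumulative-weight
band and interpolate linearly between midpoints — continuous in the weights
and equal to type-5 sample quantiles at equal weights. The Gini coefficient
is the weighted relative mean absolute difference (population convention —
the units are the complete population of subcity units, not a sample),
computed by the sorted O(n log n) identity and verified against the O(n²)
double sum. The CV uses the weighted population variance. The ICC comes
from an unweighted REML random-intercept fit (statsmodels MixedLM);
singular fits report ICC 0 with a flag. A population-weighted
method-of-moments variant (Searle's unbalanced one-way ANOVA) is available
by flag, since frequency-weighted REML is convention-dependent.

## SES association

Within each city the exposure is divided by its weighted P90–P10 range, so
the coefficient reads "years of life expectancy per P90–P10 increase in
SES" and is comparable across cities. Per-draw fits are closed-form WLS
(validated against statsmodels), with classical variances by default and an
HC0 sandwich by flag. Rubin's rules combine the m = 2000 per-draw
coefficients: T = W + (1 + 1/m)·B with a t reference at
df = (m−1)(1 + W/((1+1/m)B))²; at B = 0 the reference collapses to the
normal. Coordinates entering the spatial polynomial are centred and scaled
to unit SD before expansion for numerical conditioning.

## Synthetic data

The generator emulates the structure the analysis assumes, not any specific
city. Education is drawn first (Beta(4, 6)); mortality and registration
coverage are conditioned on it, creating both the SES→e0 gradient and the
SES→coverage confounding that motivates the undercount correction.

- Hazard: Gompertz–Makeham μ(x) = C + A·e^{Bx} with A = 5×10⁻⁵, B = 0.09,
  C = 5×10⁻⁴, giving e0 ≈ 73 (men) / 78 (women) with a ±0.175 sex log-gap —
  the level of large Latin American cities.
- SES gradient: log-rate shift `ses_beta` × (education − mean), default
  −0.6 (≈ 2.5 years of e0 across the education IQR).
- Age deviations: stationary AR(1) across the 16 age groups per unit × sex,
  default ρ = 0.6, σ = 0.15.
- Population: lognormal unit sizes (median 20 000, σ = 0.5); each
  unit × sex receives the stable age structure implied by its own
  piecewise-constant rate schedule at growth rate r = 0.01/yr (closed form
  per group). Keeping population, growth and deaths mutually consistent is
  what makes the death-distribution methods identifiable on this data.
- Counts: true deaths ~ Poisson(rate × population); reported deaths ~
  Binomial(true, coverage) with logit(coverage) linear in centred education
  (base 0.92, slope 1.5).
- True e0 is computed from the unit's true rate schedule through the same
  Gompertz-extension + life-table conventions as the estimates, so
  recovery errors measure inference, not convention mismatch.

What the generator does **not** emulate: migration, census undercount of
the population series, year-to-year mortality shocks, within-unit
heterogeneity, and spatial autocorrelation of SES or mortality
(coordinates are independent of everything else). Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not robustness to violations a real vital-registration system may exhibit.

A stationary-population fixture (`generate_stationary_population`) emits
expected (optionally Poisson) deaths exactly consistent with a stable
population at growth r, for exact-recovery tests of GGB/SEG under binomial
thinning.

## Numerical choices and degenerate inputs

- GGB needs ≥ 5 cutoff ages in the fit range; zero-covariance or
  non-positive-slope fits raise `EstimationFailure` (the pipeline then
  pools to city level).
- Non-positive rates inside the Gompertz fit range are an error; an open
  interval with m = 0 has undefined expectancy and is rejected.
- The WLS design matrix is rejected when its normal-equations condition
  number exceeds 1e10, naming the collinear columns.
- Quantiles clamp at the extreme unit values beyond the outermost band
  midpoints; p must lie strictly in (0, 1).
- `correct_deaths` requires a coverage estimate for every unit × sex
  stratum present and refuses non-positive coverage.

## Known limitations

- Uncertainty from the completeness estimate is not propagated into the
  posterior intervals — credible intervals are conditional on the applied
  correction factor (the pooled-over-draws regressions inherit this).
- The DDM two-point setup uses the first/last year of a short window;
  completeness estimates on 5-year windows are noisy for units below ~50 000
  population, which is why the pipeline supports city-level pooled
  fallbacks.
- The abridged q conversion (a = n/2) deviates from exact
  piecewise-exponential survival at very high old-age rates; the effect on
  e0 is < 0.1 years for realistic schedules (checked against a lifetime
  microsimulation).
- The mixed-model ICC treats unit medians as error-free observations;
  posterior uncertainty in e0 is not propagated into the variance
  decomposition.
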