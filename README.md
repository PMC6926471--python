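# lifegap

Small-area life expectancy estimation and inequality analysis for city
subunits, from tabulated vital-registration counts.

Cities are strikingly unequal places: life expectancy at birth can differ
by a decade or more between neighbourhoods a few kilometres apart. Measuring
those gaps from administrative data is hard for three reasons — deaths are
under-registered, and more so in poorer areas; many subcity units are small,
so crude rates fluctuate wildly; and the available age tabulations stop at
75+, truncating exactly the ages where most deaths occur. `lifegap`
implements a complete pipeline for this problem, aimed at demographers and
epidemiologists working with subnational mortality data:

1. **Undercount correction** — death-registration completeness per
   unit × sex by two death-distribution methods, generalised growth balance
   (GGB: completeness = 1/slope of the regression of entry-minus-growth
   rates on registered death rates above successive ages) and synthetic
   extinct generations (SEG: population reconstructed from deaths above
   each age under stable-population growth); combined by harmonic mean,
   truncated at 1, and death counts inflated by 1/coverage.
2. **Bayesian rate smoothing** — per city × sex, a Poisson model
   D_ua ~ Poisson(E_ua·exp(α_a + θ_ua)) with a stationary AR(1) structure
   for θ_u,· across age groups, sampled by a vectorised
   Metropolis-within-Gibbs MCMC (5000 burn-in + 20 000 iterations, 2000
   retained draws by default) with split-R̂/ESS convergence gates.
3. **Life tables** — each draw's rate schedule is extended past 75+ with a
   Gompertz hazard m(x) = A·e^{Bx} fitted to ages 45–70, then run through an
   abridged life table (q = n·m/(1+(n−a)m)); the unit's life expectancy is
   the median of the 2000 per-draw e0 values (e40/e60 available).
4. **Inequality metrics** — population-weighted P90–P10 gap, Gini
   coefficient and coefficient of variation of unit life expectancy within
   each city; ICC of units nested in cities from a REML random-intercept
   model.
5. **SES association** — within each city, weighted least squares of unit
   life expectancy on education (or piped water / overcrowding) scaled to
   its weighted P90–P10 range, adjusted for built-up fraction, refit on
   every posterior draw and pooled with Rubin's rules
   (T = W + (1 + 1/m)·B).

Because real subcity vital-registration microdata are restricted, the
package ships a synthetic-city generator (`lifegap.synthetic`) that
reproduces the statistical structure the pipeline assumes — SES-graded
mortality, AR(1) age deviations, SES-linked undercounting, stable
population growth — with full ground truth, so every stage is testable end
to end. See `docs/methods.md` for the statistical details and assumptions.

## Worked example

Estimating registration completeness on a stationary synthetic population
whose deaths are 75% registered (`examples/02_completeness.py`):

```text
true completeness: 0.750
GGB estimate:      0.757  (regression slope 1.321, intercept 0.00010)
SEG estimate:      0.764
harmonic mean (truncated at 1): 0.760
death counts are then inflated by 1/coverage = 1.315
```

Both methods recover the thinning rate to within a percentage point; the
near-zero GGB intercept says the two population profiles are equally
covered. Inequality arithmetic and a pooled SES regression
(`examples/04_inequality_and_ses.py`):

```text
men, Panama City: 71.3 to 86.3 -> P90-P10 gap 15.0 years
synthetic city: gap 15.8 y, gini 0.0376, cv 0.0694
pooled education effect: 4.04 years per P90-P10 (95% CI 3.31 to 4.77; true 4.0)
```

The first line is the decile arithmetic for a published city table: the
ninth-decile unit outlives the first-decile unit by 15 years. The last line
regresses 200 simulated posterior e0 draws on scaled education and pools
with Rubin's rules — the interval covers the generative effect of 4 years
per P90–P10 of education. The other scripts in `examples/` cover city
simulation, smoothing + life expectancy with credible intervals, and the
full two-city pipeline (each prints the numbers it computes and what they
mean).

## Command line

A thin CLI wraps the library for shell use:

```sh
lifegap simulate --n-cities 2 --n-units 20 --seed 1 --outdir data/
lifegap run-all --deaths data/deaths.csv --population data/population.csv \
    --units data/units.csv --outdir report/ --seed 1
```

`run-all` writes `coverage.csv`, `life_expectancy.csv`, `inequality.csv`,
`icc.csv`, `association.csv` and a `manifest.json` (config echo, seed,
convergence warnings, timings), and prints the per-city summary table.
Sensitivity analyses are flags: `--undercount-mode
{correct,drop_below_0.9,no_truncation}`, `--outcome-age {0,40,60}`,
`--exposure {education,water,overcrowding}`, `--spatial-adjust`.

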