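"""Estimate death-registration completeness with GGB and SEG.

A stationary synthetic population with a known hazard is thinned to 75%
registration; both death-distribution methods should recover ~0.75, and
their truncated harmonic mean is the correction factor's denominator.
"""

import numpy as np

from lifegap import SyntheticCityConfig, combine_coverage, generate_stationary_population
from lifegap.coverage import ggb_coverage, seg_coverage

cfg = SyntheticCityConfig(n_units=2, population_scale=100_000, growth_rate=0.01)
deaths, pop = generate_stationary_population(cfg)
scheme = deaths.scheme
years = pop.years

profile = lambda y: (
    pop.df[pop.df.year == y].set_index("age_lower").population
    .reindex(scheme.lower_bounds).to_numpy()
)
d = deaths.pivot("u1", "male").to_numpy() / len(deaths.years)

true_c = 0.75
d_reported = true_c * d  # 25% of deaths never registered

ggb, slope, intercept, _ = ggb_coverage(
    profile(years[0]), profile(years[-1]), d_reported, years[-1] - years[0], scheme=scheme
)
seg, _ = seg_coverage(
    profile(years[0]), profile(years[-1]), d_reported, years[-1] - years[0], scheme=scheme
)
combined = combine_coverage(ggb, seg)

print(f"true completeness: {true_c:.3f}")
print(f"GGB estimate:      {ggb:.3f}  (regression slope {slope:.3f}, intercept {intercept:.5f})")
print(f"SEG estimate:      {seg:.3f}")
print(f"harmonic mean (truncated at 1): {combined:.3f}")
print()
print(f"death counts are then inflated by 1/coverage = {1 / combined:.3f}")
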