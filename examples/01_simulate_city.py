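"""Generate one synthetic city and inspect its structure and ground truth.

The generator emulates sub-city vital-registration data: an education
gradient in mortality, AR(1)-correlated age deviations per unit, and
SES-linked death-registration undercounting.
"""

from lifegap import SyntheticCityConfig, generate_city

cfg = SyntheticCityConfig(n_units=8, seed=42)
deaths_true, deaths_reported, population, attrs, truth = generate_city(cfg)

print(f"units: {cfg.n_units}, years: {sorted(deaths_true.df.year.unique())}")
print(f"true deaths:     {deaths_true.df.deaths.sum():9.0f}")
print(f"reported deaths: {deaths_reported.df.deaths.sum():9.0f}  (undercounted)")
print()
print("per-unit truth (male):")
t = truth[truth.sex == "male"][["unit_id", "true_e0", "true_coverage"]]
t = t.merge(attrs.df[["unit_id", "education"]], on="unit_id")
print(t.round(3).to_string(index=False))
print()
print("Higher-education units live longer (ses_beta < 0) and register a")
print("larger share of their deaths (coverage_ses_slope > 0).")
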