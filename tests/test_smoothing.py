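import numpy as np
import pandas as pd
import pytest

from lifegap.data_model import AgeGroupScheme, DeathTable, PopulationTable, ValidationError
from lifegap.smoothing import (
    PosteriorRateDraws,
    SmoothingConfig,
    fit_smoothing_model,
    posterior_summary,
)


def _tables(D, E, scheme, sex="male", year=2011):
    rows_d, rows_p = [], []
    for u in range(D.shape[0]):
        for a, lo in enumerate(scheme.lower_bounds):
            rows_d.append((f"u{u:02d}", sex, lo, year, float(D[u, a])))
            rows_p.append((f"u{u:02d}", sex, lo, year, float(E[u, a])))
    cols = ["unit_id", "sex", "age_lower", "year"]
    return (
        DeathTable(pd.DataFrame(rows_d, columns=cols + ["deaths"]), scheme),
        PopulationTable(pd.DataFrame(rows_p, columns=cols + ["population"]), scheme),
    )


class TestConfig:
    def test_draws_cannot_exceed_iterations(self):
        with pytest.raises(ValidationError):
            SmoothingConfig(iterations=100, chains=1, n_draws=200)


class TestFit:
    def test_dominant_unit_tracks_crude_rates(self, scheme):
        """With PY=1e7 per cell the likelihood overwhelms prior and shrinkage."""
        rng = np.random.default_rng(0)
        true = 5e-5 * np.exp(0.09 * scheme.midpoints()) + 5e-4
        E = np.full((3, scheme.n_groups), 1e7)
        E[1:] = 1e4  # two small companions
        D = rng.poisson(true[None, :] * E).astype(float)
        deaths, pop = _tables(D, E, scheme)
        cfg = SmoothingConfig(burn_in=800, iterations=1500, n_draws=500, chains=2, seed=4)
        post = fit_smoothing_model(deaths, pop, cfg)
        crude = D[0] / E[0]
        post_mean = post.values[:, 0, :].mean(axis=0)
        assert np.max(np.abs(post_mean / crude - 1)) < 0.02

    def test_zero_death_unit_shrinks_to_positive_rates(self, scheme):
        rng = np.random.default_rng(1)
        true = 5e-5 * np.exp(0.09 * scheme.midpoints()) + 5e-4
        E = np.full((4, scheme.n_groups), 2e5)
        E[0] = 50.0  # tiny unit, will see zero deaths at young ages
        D = rng.poisson(true[None, :] * E).astype(float)
        D[0] = 0.0
        deaths, pop = _tables(D, E, scheme)
        cfg = SmoothingConfig(burn_in=500, iterations=1000, n_draws=400, chains=1, seed=2)
        post = fit_smoothing_model(deaths, pop, cfg)
        rates0 = post.values[:, 0, :]
        assert np.all(rates0 > 0)
        # shrinkage toward the city age curve exp(alpha_a)
        city_curve = np.exp(post.alpha).mean(axis=0)
        assert np.median(np.abs(np.log(rates0.mean(0) / city_curve))) < 1.0

    def test_shrinkage_stronger_for_smaller_units(self, scheme):
        """Same crude rates, 10x less exposure: posterior pulled further."""
        rng = np.random.default_rng(3)
        true = 5e-5 * np.exp(0.09 * scheme.midpoints()) + 5e-4
        # both outlier units have doubled mortality; E differs 10x
        E = np.full((10, scheme.n_groups), 1e5)
        E[1] = 1e4
        D = rng.poisson(true[None, :] * E).astype(float)
        D[0] = 2 * true * E[0]
        D[1] = 2 * true * E[1]
        deaths, pop = _tables(D, E, scheme)
        cfg = SmoothingConfig(burn_in=800, iterations=1500, n_draws=500, chains=1, seed=5)
        post = fit_smoothing_model(deaths, pop, cfg)
        crude_big = D[0] / E[0]
        crude_small = D[1] / E[1]
        gap_big = np.abs(np.log(post.values[:, 0, :].mean(0) / crude_big)).mean()
        gap_small = np.abs(np.log(post.values[:, 1, :].mean(0) / crude_small)).mean()
        assert gap_small > gap_big

    def test_relabelling_units_leaves_posterior_unchanged(self, city_bundle):
        """Unit labels carry no information: a rank-preserving relabelling
        reproduces the posterior exactly (same seed, same data order)."""
        deaths = city_bundle["deaths"]
        male = DeathTable(deaths.df[deaths.df.sex == "male"], deaths.scheme)
        pop = city_bundle["population"]
        cfg = SmoothingConfig(burn_in=200, iterations=300, n_draws=100, chains=1, seed=11)
        post = fit_smoothing_model(male, pop, cfg)

        mapping = {u: f"z{i:02d}" for i, u in enumerate(post.units)}
        male2 = DeathTable(male.df.assign(unit_id=male.df.unit_id.map(mapping)), deaths.scheme)
        pop2 = PopulationTable(pop.df.assign(unit_id=pop.df.unit_id.map(mapping)), pop.scheme)
        post2 = fit_smoothing_model(male2, pop2, cfg)
        assert post2.units == [mapping[u] for u in post.units]
        assert np.allclose(post.values, post2.values)

    def test_reordering_units_is_statistically_equivalent(self, city_bundle, male_fit):
        """Feeding the units in a different order changes the MCMC stream but
        not the inference: posterior means agree within Monte Carlo error."""
        deaths = city_bundle["deaths"]
        male = DeathTable(deaths.df[deaths.df.sex == "male"], deaths.scheme)
        pop = city_bundle["population"]
        mapping = {u: f"z{i:02d}" for i, u in enumerate(reversed(male_fit.units))}
        male2 = DeathTable(male.df.assign(unit_id=male.df.unit_id.map(mapping)), deaths.scheme)
        pop2 = PopulationTable(pop.df.assign(unit_id=pop.df.unit_id.map(mapping)), pop.scheme)
        cfg = SmoothingConfig(burn_in=800, iterations=1500, n_draws=500, chains=2, seed=99)
        post2 = fit_smoothing_model(male2, pop2, cfg)
        perm = [post2.units.index(mapping[u]) for u in male_fit.units]
        m1 = np.log(male_fit.values.mean(axis=0))
        m2 = np.log(post2.values[:, perm, :].mean(axis=0))
        assert np.median(np.abs(m1 - m2)) < 0.05

    def test_multiple_sexes_require_selection(self, city_bundle):
        with pytest.raises(ValidationError):
            fit_smoothing_model(
                city_bundle["deaths"], city_bundle["population"], SmoothingConfig(seed=0)
            )

    def test_draw_shapes_and_positivity(self, male_fit):
        assert isinstance(male_fit, PosteriorRateDraws)
        n_draws, n_units, n_age = male_fit.values.shape
        assert n_draws == 500 and n_units == len(male_fit.units) and n_age == 16
        assert np.all(male_fit.values > 0)
        assert {"rhat_alpha_max", "ess_alpha_min"} <= male_fit.diagnostics.keys()


class TestPosteriorSummary:
    def test_quantiles_match_sort_oracle(self, male_fit):
        s = posterior_summary(male_fit)
        u, a = 3, 8
        col = np.sort(male_fit.values[:, u, a])
        row = s[(s.unit_id == male_fit.units[u]) & (s.age_lower == male_fit.scheme.lower_bounds[a])]
        assert row.rate_median.iloc[0] == pytest.approx(np.quantile(col, 0.5))
        assert row.rate_lo95.iloc[0] == pytest.approx(np.quantile(col, 0.025))
        assert row.rate_hi95.iloc[0] == pytest.approx(np.quantile(col, 0.975))

    def test_degenerate_draws(self, scheme):
        vals = np.full((5, 2, scheme.n_groups), 0.01)
        draws = PosteriorRateDraws(
            values=vals, units=["a", "b"], sex="male", scheme=scheme,
            alpha=np.zeros((5, scheme.n_groups)), rho=np.zeros(5), sigma=np.ones(5),
        )
        s = posterior_summary(draws)
        assert np.allclose(s.rate_median, 0.01)
        assert np.allclose(s.rate_hi95 - s.rate_lo95, 0.0)
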