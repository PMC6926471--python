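import numpy as np
import pytest

from lifegap.data_model import AgeGroupScheme, DeathTable
from lifegap.smoothing import SmoothingConfig, fit_smoothing_model
from lifegap.synthetic import SyntheticCityConfig, generate_city


@pytest.fixture(scope="session")
def scheme():
    return AgeGroupScheme()


@pytest.fixture(scope="session")
def city_bundle():
    """One mid-size synthetic city with complete registration."""
    cfg = SyntheticCityConfig(
        n_units=12, seed=42, population_scale=30_000,
        coverage_base=1.0, coverage_ses_slope=0.0,
    )
    deaths_true, deaths_rep, population, attrs, truth = generate_city(cfg)
    return {
        "config": cfg,
        "deaths": deaths_true,
        "population": population,
        "attrs": attrs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def undercount_bundle():
    """A city with SES-linked undercounting, for coverage-correction tests."""
    cfg = SyntheticCityConfig(n_units=10, seed=7, population_scale=80_000)
    deaths_true, deaths_rep, population, attrs, truth = generate_city(cfg)
    return {
        "config": cfg,
        "deaths_true": deaths_true,
        "deaths_rep": deaths_rep,
        "population": population,
        "attrs": attrs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def male_fit(city_bundle):
    """Reduced-schedule posterior for the male stratum of the test city."""
    deaths = city_bundle["deaths"]
    male = DeathTable(deaths.df[deaths.df.sex == "male"], deaths.scheme)
    cfg = SmoothingConfig(burn_in=800, iterations=1500, n_draws=500, chains=2, seed=99)
    return fit_smoothing_model(male, city_bundle["population"], cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
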