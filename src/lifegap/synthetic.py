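"""Synthetic multi-city mortality datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a Gompertz-Makeham baseline hazard, an SES (education) gradient in
log mortality, mean-zero stationary AR(1) deviations of log rates across
age groups within each unit, exponential population growth, Poisson death
counts, and SES-linked death-registration undercount via binomial thinning.
Every draw flows from one seeded :class:`numpy.random.Generator`, so a
given config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lifegap.data_model import AgeGroupScheme, DeathTable, PopulationTable, UnitAttributes, ValidationError
from lifegap import lifetables


@dataclass(frozen=True)
class SyntheticCityConfig:
    """Generative parameters for one synthetic city.

    Mortality: hazard at age x is ``makeham_C + gompertz_A*exp(gompertz_B*x)``
    multiplied on the log scale by an education effect and AR(1) age
    deviations.  ``ses_beta`` is the change in log hazard per unit increase
    in the education proportion (negative = protective).  Registration
    coverage is logit-linear in education around ``coverage_base``.
    """

    n_units: int = 30
    years: int = 5
    start_year: int = 2011
    population_scale: float = 20_000.0
    population_sigma: float = 0.5
    education_dist: tuple = (4.0, 6.0)
    gompertz_A: float = 5e-5
    gompertz_B: float = 0.09
    makeham_C: float = 5e-4
    sex_log_gap: float = 0.35
    ses_beta: float = -0.6
    ar_rho: float = 0.6
    ar_sigma: float = 0.15
    coverage_base: float = 0.92
    coverage_ses_slope: float = 1.5
    growth_rate: float = 0.01
    city_id: str = "city1"
    seed: int = 0
    scheme: AgeGroupScheme = field(default_factory=AgeGroupScheme)

    def __post_init__(self):
        if self.gompertz_A <= 0 or self.gompertz_B < 0:
            raise ValidationError("gompertz_A must be > 0 and gompertz_B >= 0")
        if not (0 < self.coverage_base <= 1):
            raise ValidationError("coverage_base must be in (0, 1]")
        if abs(self.ar_rho) >= 1 or self.ar_sigma < 0:
            raise ValidationError("need |ar_rho| < 1 and ar_sigma >= 0")


def _hazard(cfg: SyntheticCityConfig, x):
    return cfg.makeham_C + cfg.gompertz_A * np.exp(cfg.gompertz_B * np.asarray(x, float))


def _ar1(rng, n_series, n, rho, sigma):
    """Stationary mean-zero AR(1) paths, shape (n_series, n)."""
    theta = np.zeros((n_series, n))
    if sigma == 0:
        return theta
    theta[:, 0] = rng.normal(0.0, sigma / np.sqrt(1 - rho**2), n_series)
    eps = rng.normal(0.0, sigma, (n_series, n - 1))
    for a in range(1, n):
        theta[:, a] = rho * theta[:, a - 1] + eps[:, a - 1]
    return theta


def _stable_age_structure(cfg: SyntheticCityConfig, dx: float = 0.1, max_age: float = 110.0):
    """Stable-population density on a fine grid: n(x) ∝ exp(-r x) S(x)."""
    x = np.arange(0.0, max_age, dx)
    mu = _hazard(cfg, x + dx / 2)
    cum = np.concatenate([[0.0], np.cumsum(mu * dx)])[:-1]
    surv = np.exp(-cum)
    dens = np.exp(-cfg.growth_rate * x) * surv
    return x, dens, mu


def _aggregate(scheme: AgeGroupScheme, x, values, dx):
    """Integrate a fine-grid density into the abridged age groups."""
    lows = np.asarray(scheme.lower_bounds, float)
    highs = np.append(lows[1:], np.inf)
    out = np.empty(scheme.n_groups)
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        sel = (x >= lo) & (x < hi)
        out[i] = values[sel].sum() * dx
    return out


def _stable_shares_from_rates(rates: np.ndarray, scheme: AgeGroupScheme, r: float) -> np.ndarray:
    """Stable-population group shares consistent with a piecewise-constant
    hazard (the unit's own rate schedule) growing at rate r.

    Within a closed group [lo, lo+w) with hazard m, the group population is
    S(lo)*exp(-r*lo)*(1 - exp(-(m+r)*w)) / (m+r); the open group integrates
    the same expression to infinity.  Keeping population and deaths mutually
    consistent is what makes the death-distribution methods identifiable on
    this synthetic data.
    """
    w = scheme.group_width
    lows = np.asarray(scheme.lower_bounds, dtype=float)
    shares = np.empty(scheme.n_groups)
    S = 1.0
    for i, (lo, m) in enumerate(zip(lows, rates)):
        k = m + r
        if i < scheme.n_groups - 1:
            shares[i] = S * np.exp(-r * lo) * (1 - np.exp(-k * w)) / k
            S *= np.exp(-m * w)
        else:
            shares[i] = S * np.exp(-r * lo) / k
    return shares / shares.sum()


def _true_e0(rates: np.ndarray, scheme: AgeGroupScheme, age: int = 0) -> float:
    fit = lifetables.fit_gompertz(rates, scheme)
    ext_rates, ext_scheme = lifetables.extrapolate_rates(rates, fit, scheme)
    table = lifetables.build_life_table(ext_rates, ext_scheme)
    return lifetables.life_expectancy_at(table, age)


def generate_city(config: SyntheticCityConfig):
    """Simulate one city: true deaths, reported deaths, population, attributes, truth.

    Returns
    -------
    (DeathTable, DeathTable, PopulationTable, UnitAttributes, DataFrame)
        True deaths, coverage-thinned reported deaths, population series,
        unit attributes, and a truth record with one row per unit x sex
        holding the true rate schedule, true life expectancy at birth, and
        true registration coverage.
    """
    cfg = config
    if cfg.n_units < 2:
        raise ValidationError("generate_city needs n_units >= 2")
    rng = np.random.default_rng(cfg.seed)
    scheme = cfg.scheme
    n_age = scheme.n_groups
    mids = scheme.midpoints()
    units = [f"{cfg.city_id}_u{i:03d}" for i in range(cfg.n_units)]

    # SES first; mortality and coverage are conditioned on it.
    edu = rng.beta(*cfg.education_dist, cfg.n_units)
    edu_c = edu - edu.mean()
    water = np.clip(0.5 + 0.8 * edu_c + rng.normal(0, 0.08, cfg.n_units), 0.01, 0.99)
    crowd = np.clip(0.3 - 0.6 * edu_c + rng.normal(0, 0.08, cfg.n_units), 0.01, 0.99)
    builtup = rng.beta(5, 2, cfg.n_units)
    lon = rng.uniform(-58.6, -58.3, cfg.n_units)
    lat = rng.uniform(-34.8, -34.5, cfg.n_units)

    if cfg.coverage_base >= 1.0 and cfg.coverage_ses_slope == 0:
        cov = np.ones(cfg.n_units)
    else:
        base = min(cfg.coverage_base, 1 - 1e-9)
        logit_c = np.log(base / (1 - base)) + cfg.coverage_ses_slope * edu_c
        cov = np.clip(1 / (1 + np.exp(-logit_c)), 1e-6, 1.0)

    base_log = np.log(_hazard(cfg, mids))
    sex_off = {"male": cfg.sex_log_gap / 2, "female": -cfg.sex_log_gap / 2}

    # Population: lognormal unit sizes, per-unit stable age structure
    # consistent with the unit's own mortality, 50/50 sexes, exponential
    # growth over the window.
    unit_sizes = rng.lognormal(np.log(cfg.population_scale), cfg.population_sigma, cfg.n_units)
    years = np.arange(cfg.start_year, cfg.start_year + cfg.years)

    true_rows, rep_rows, pop_rows, truth_rows = [], [], [], []
    for s in ("male", "female"):
        theta = _ar1(rng, cfg.n_units, n_age, cfg.ar_rho, cfg.ar_sigma)
        rates = np.exp(base_log[None, :] + sex_off[s] + cfg.ses_beta * edu_c[:, None] + theta)
        for u in range(cfg.n_units):
            age_shares = _stable_shares_from_rates(rates[u], scheme, cfg.growth_rate)
            pop_base = unit_sizes[u] * age_shares / 2.0
            for t, yr in enumerate(years):
                pop = pop_base * np.exp(cfg.growth_rate * t)
                lam = rates[u] * pop
                d_true = rng.poisson(lam).astype(float)
                d_rep = rng.binomial(d_true.astype(int), cov[u]).astype(float)
                for a, lo in enumerate(scheme.lower_bounds):
                    pop_rows.append((units[u], s, lo, yr, pop[a]))
                    true_rows.append((units[u], s, lo, yr, d_true[a]))
                    rep_rows.append((units[u], s, lo, yr, d_rep[a]))
            truth_rows.append(
                {
                    "unit_id": units[u],
                    "sex": s,
                    "true_e0": _true_e0(rates[u], scheme),
                    "true_coverage": cov[u],
                    **{f"rate_{lo}": rates[u, a] for a, lo in enumerate(scheme.lower_bounds)},
                }
            )

    cols = ["unit_id", "sex", "age_lower", "year"]
    deaths_true = DeathTable(pd.DataFrame(true_rows, columns=cols + ["deaths"]), scheme)
    deaths_rep = DeathTable(pd.DataFrame(rep_rows, columns=cols + ["deaths"]), scheme)
    population = PopulationTable(pd.DataFrame(pop_rows, columns=cols + ["population"]), scheme)
    attrs = UnitAttributes(
        pd.DataFrame(
            {
                "unit_id": units,
                "city_id": cfg.city_id,
                "education": edu,
                "water": water,
                "overcrowding": crowd,
                "builtup": builtup,
                "lon": lon,
                "lat": lat,
            }
        )
    )
    truth = pd.DataFrame(truth_rows)
    return deaths_true, deaths_rep, population, attrs, truth


def generate_stationary_population(
    config: SyntheticCityConfig,
    poisson: bool = False,
    rng: np.random.Generator | None = None,
    unit_id: str = "u1",
    sex: str = "male",
):
    """Demographically consistent stable population for one unit.

    The age structure is proportional to exp(-r x) S(x) under the config's
    Gompertz-Makeham hazard, deaths are consistent with that hazard, and
    every age group grows at exactly ``growth_rate`` per year.  Counts are
    expected values unless ``poisson=True`` (then deaths are Poisson draws).
    Serves as an exact-recovery fixture for the death-distribution methods.
    """
    cfg = config
    scheme = cfg.scheme
    x, dens, mu = _stable_age_structure(cfg)
    dx = x[1] - x[0]
    pop_profile = _aggregate(scheme, x, dens, dx)
    death_profile = _aggregate(scheme, x, dens * mu, dx)
    scale = cfg.population_scale / pop_profile.sum()
    pop_profile = pop_profile * scale
    death_profile = death_profile * scale

    if poisson and rng is None:
        rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.start_year, cfg.start_year + cfg.years)
    pop_rows, death_rows = [], []
    for t, yr in enumerate(years):
        g = np.exp(cfg.growth_rate * t)
        d = death_profile * g
        if poisson:
            d = rng.poisson(d).astype(float)
        for a, lo in enumerate(scheme.lower_bounds):
            pop_rows.append((unit_id, sex, lo, yr, pop_profile[a] * g))
            death_rows.append((unit_id, sex, lo, yr, d[a]))
    cols = ["unit_id", "sex", "age_lower", "year"]
    deaths = DeathTable(pd.DataFrame(death_rows, columns=cols + ["deaths"]), scheme)
    population = PopulationTable(pd.DataFrame(pop_rows, columns=cols + ["population"]), scheme)
    return deaths, population


def generate_study(configs: list[SyntheticCityConfig]):
    """Concatenate several cities into one study bundle (reported deaths)."""
    parts = [generate_city(c) for c in configs]
    scheme = configs[0].scheme
    deaths_true = DeathTable(pd.concat([p[0].df for p in parts], ignore_index=True), scheme)
    deaths_rep = DeathTable(pd.concat([p[1].df for p in parts], ignore_index=True), scheme)
    population = PopulationTable(pd.concat([p[2].df for p in parts], ignore_index=True), scheme)
    attrs = UnitAttributes(pd.concat([p[3].df for p in parts], ignore_index=True))
    truth = pd.concat([p[4] for p in parts], ignore_index=True)
    return deaths_true, deaths_rep, population, attrs, truth


def write_bundle(outdir, deaths: DeathTable, population: PopulationTable, attrs: UnitAttributes, truth=None):
    """Emit deaths.csv, population.csv, units.csv (and truth.csv) to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    deaths.to_csv(out / "deaths.csv")
    population.to_csv(out / "population.csv")
    attrs.to_csv(out / "units.csv")
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
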