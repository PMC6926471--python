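"""Death-registration completeness via death-distribution methods.

Two classical estimators compare the age distribution of registered deaths
with intercensal population change under stable-population assumptions:

* **GGB** (generalised growth balance): above each cutoff age a the entry
  rate minus the growth rate equals the true death rate, so regressing
  b(a) - r(a+) on the *registered* death rate d(a+) gives a line whose
  slope is 1/completeness and whose intercept reflects relative census
  coverage change.
* **SEG** (synthetic extinct generations): the population at each exact age
  is reconstructed from registered deaths above that age, each projected
  back by the age-specific growth rate; completeness is the ratio of
  reconstructed to observed population.

Estimates from the two methods are combined by their harmonic mean and
truncated at 1, and death counts are inflated by 1/coverage.  The two
population profiles are taken from the first and last years of the
available population series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from lifegap.data_model import AgeGroupScheme, DeathTable, PopulationTable, ValidationError

DEFAULT_FIT_RANGE = (15, 65)


class EstimationFailure(RuntimeError):
    """A death-distribution method could not produce a usable estimate."""


@dataclass
class CoverageEstimate:
    """Per unit x sex completeness estimates and their combination."""

    unit_id: str
    sex: str
    ggb: float
    seg: float
    combined: float
    truncated: float
    fit_range: tuple = DEFAULT_FIT_RANGE
    flag: str = "ok"
    diagnostics: dict = field(default_factory=dict)


def _cutoff_quantities(pop_t1, pop_t2, deaths, window, scheme):
    """Exact-age densities, open-interval aggregates and growth rates."""
    p1 = np.asarray(pop_t1, dtype=float)
    p2 = np.asarray(pop_t2, dtype=float)
    d = np.asarray(deaths, dtype=float)
    n = scheme.n_groups
    w = scheme.group_width
    if not (len(p1) == len(p2) == len(d) == n):
        raise ValidationError("profiles must cover the full age scheme")
    # persons per year of age at exact age a (cutoffs a = bounds[1:]), per census
    dens1 = (p1[:-1] + p1[1:]) / (2.0 * w)
    dens2 = (p2[:-1] + p2[1:]) / (2.0 * w)
    cum1 = np.cumsum(p1[::-1])[::-1]
    cum2 = np.cumsum(p2[::-1])[::-1]
    cumd = np.cumsum(d[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r_plus = np.log(cum2 / cum1) / window
    return dens1, dens2, cum1, cum2, cumd, r_plus


def _fit_cutoffs(scheme, fit_range):
    bounds = np.asarray(scheme.lower_bounds)
    cut = bounds[1:]
    return cut, (cut >= fit_range[0]) & (cut <= fit_range[1])


def ggb_coverage(pop_t1, pop_t2, deaths, window, fit_range=DEFAULT_FIT_RANGE,
                 scheme: AgeGroupScheme | None = None, method: str = "tls"):
    """Generalised growth balance completeness estimate.

    Parameters
    ----------
    pop_t1, pop_t2
        Age profiles (length = number of age groups) at the two time points.
    deaths
        Mean annual registered deaths per age group over the window.
    window
        Years between the two population profiles.
    method
        ``"tls"`` (orthogonal regression, default) or ``"ols"``.

    Returns
    -------
    (completeness, slope, intercept, diagnostics)
    """
    scheme = scheme or AgeGroupScheme()
    dens1, dens2, cum1, cum2, cumd, r_plus = _cutoff_quantities(pop_t1, pop_t2, deaths, window, scheme)
    cut, mask = _fit_cutoffs(scheme, fit_range)
    if mask.sum() < 5:
        raise ValidationError("need at least 5 cutoff ages inside the GGB fit range")
    n_plus = np.sqrt(cum1[1:] * cum2[1:])          # mid-period person-years per year above a
    dens = np.sqrt(dens1 * dens2)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = dens / n_plus
        dr = cumd[1:] / n_plus
        y = b - r_plus[1:]
    x, yv = dr[mask], y[mask]
    if not (np.isfinite(x).all() and np.isfinite(yv).all()) or np.all(x == 0):
        raise EstimationFailure("degenerate GGB inputs (zero deaths or empty ages)")
    if method == "ols":
        slope, intercept = np.polyfit(x, yv, 1)
    else:  # orthogonal (total least squares)
        sxx = np.var(x)
        syy = np.var(yv)
        sxy = np.cov(x, yv, bias=True)[0, 1]
        if sxy == 0:
            raise EstimationFailure("GGB regression has zero covariance")
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
        intercept = yv.mean() - slope * x.mean()
    diagnostics = {
        "cutoffs": cut[mask],
        "death_rate": x,
        "entry_minus_growth": yv,
        "slope": float(slope),
        "intercept": float(intercept),
    }
    if slope <= 0:
        raise EstimationFailure(f"GGB slope {slope:.3f} <= 0")
    return 1.0 / float(slope), float(slope), float(intercept), diagnostics


def _gompertz_open_expectancy(rates, scheme, open_age, fit_ages=(45, 70)):
    """Remaining expectancy at the open age under a Gompertz fit to 45-70 rates."""
    from lifegap.lifetables import fit_gompertz

    fit = fit_gompertz(np.maximum(rates, 1e-12), scheme, fit_ages)
    surv = lambda t: np.exp(-(fit.A / fit.B) * (np.exp(fit.B * (open_age + t)) - np.exp(fit.B * open_age)))
    e_open, _ = quad(surv, 0, 60, limit=200)
    return e_open


def seg_coverage(pop_t1, pop_t2, deaths, window, fit_range=DEFAULT_FIT_RANGE,
                 scheme: AgeGroupScheme | None = None, delta: float = 0.0,
                 summary: str = "mean"):
    """Synthetic extinct generations completeness estimate.

    The population at each exact age a is reconstructed from registered
    deaths above a, projecting each death back by the age-specific growth
    rate; the open interval is closed by a Gompertz hazard fitted to the
    observed 45-70 rates.  Completeness is the mean (or median) over the
    fit range of reconstructed / observed group populations.

    ``delta`` optionally removes a relative census-coverage change (the
    GGB intercept): the second profile is scaled by exp(-delta * window).

    Returns ``(completeness, diagnostics)``.
    """
    scheme = scheme or AgeGroupScheme()
    p1 = np.asarray(pop_t1, dtype=float)
    p2 = np.asarray(pop_t2, dtype=float) * np.exp(-delta * window)
    d = np.asarray(deaths, dtype=float)
    if d.sum() <= 0:
        raise EstimationFailure("no registered deaths; SEG undefined")
    w = scheme.group_width
    n = scheme.n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        r_age = np.log(p2 / p1) / window
    r_age = np.where(np.isfinite(r_age), r_age, 0.0)

    pop_bar = np.sqrt(p1 * p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        crude = np.where(pop_bar > 0, d / pop_bar, 0.0)
    e_open = _gompertz_open_expectancy(crude, scheme, scheme.open_lower)
    re = r_age[-1] * e_open
    n_hat = np.empty(n)  # exact-age population density (persons reaching age a per year)
    n_hat[-1] = d[-1] * (np.exp(re) - re**2 / 6.0)
    for i in range(n - 2, -1, -1):
        n_hat[i] = n_hat[i + 1] * np.exp(w * r_age[i]) + d[i] * np.exp(w / 2.0 * r_age[i])

    # reconstructed vs observed population per closed group
    seg_group = (n_hat[:-1] + n_hat[1:]) * w / 2.0
    obs_group = pop_bar[:-1]
    bounds = np.asarray(scheme.lower_bounds[:-1])
    mask = (bounds >= fit_range[0]) & (bounds <= fit_range[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(obs_group > 0, seg_group / obs_group, np.nan)
    sel = ratios[mask]
    if not np.isfinite(sel).any():
        raise EstimationFailure("no usable SEG age groups in fit range")
    completeness = float(np.nanmean(sel) if summary == "mean" else np.nanmedian(sel))
    if completeness <= 0:
        raise EstimationFailure("non-positive SEG completeness")
    diagnostics = {"age_ratios": ratios, "ages": np.asarray(scheme.lower_bounds[:-1]), "e_open": e_open}
    return completeness, diagnostics


def combine_coverage(ggb: float, seg: float) -> float:
    """Harmonic mean of the two method estimates, truncated at 1."""
    if ggb <= 0 or seg <= 0:
        raise ValidationError("coverage estimates must be positive")
    return min(2.0 / (1.0 / ggb + 1.0 / seg), 1.0)


def _profiles(deaths: DeathTable, population: PopulationTable, unit: str, sex: str):
    pop_years = population.years
    t1, t2 = pop_years[0], pop_years[-1]
    window = t2 - t1
    pdf = population.df
    sel = (pdf.unit_id == unit) & (pdf.sex == sex)
    p1 = (
        pdf[sel & (pdf.year == t1)].set_index("age_lower")["population"]
        .reindex(population.scheme.lower_bounds, fill_value=0.0).to_numpy()
    )
    p2 = (
        pdf[sel & (pdf.year == t2)].set_index("age_lower")["population"]
        .reindex(population.scheme.lower_bounds, fill_value=0.0).to_numpy()
    )
    d = deaths.pivot(unit, sex).to_numpy() / len(deaths.years)
    return p1, p2, d, window


def estimate_coverage(
    deaths: DeathTable,
    population: PopulationTable,
    fit_range=DEFAULT_FIT_RANGE,
    city_of: dict | None = None,
    ggb_method: str = "tls",
    seg_delta_from_ggb: bool = False,
) -> pd.DataFrame:
    """Run GGB + SEG per unit x sex and combine.

    Units where either method fails fall back to the pooled city x sex
    estimate (all units pooled when no city map is given), flagged
    ``"pooled_fallback"``.

    Returns a DataFrame with columns unit_id, sex, ggb, seg, combined,
    truncated, fit_lo, fit_hi, flag.
    """
    scheme = deaths.scheme
    rows = []
    pooled_cache: dict = {}

    def run(p1, p2, d, window):
        g, slope, intercept, gd = ggb_coverage(p1, p2, d, window, fit_range, scheme, ggb_method)
        delta = intercept if seg_delta_from_ggb else 0.0
        s, sd = seg_coverage(p1, p2, d, window, fit_range, scheme, delta=delta)
        return g, s

    def pooled(city, sex):
        key = (city, sex)
        if key not in pooled_cache:
            members = [u for u in deaths.units if (city_of or {}).get(u, "_all") == city]
            p1 = p2 = d = None
            for u in members:
                a, b, c, window = _profiles(deaths, population, u, sex)
                p1 = a if p1 is None else p1 + a
                p2 = b if p2 is None else p2 + b
                d = c if d is None else d + c
            pooled_cache[key] = run(p1, p2, d, window)
        return pooled_cache[key]

    for unit in deaths.units:
        for sex in sorted(deaths.df.loc[deaths.df.unit_id == unit, "sex"].unique()):
            p1, p2, d, window = _profiles(deaths, population, unit, sex)
            flag = "ok"
            try:
                g, s = run(p1, p2, d, window)
            except (EstimationFailure, ValidationError):
                city = (city_of or {}).get(unit, "_all")
                g, s = pooled(city, sex)
                flag = "pooled_fallback"
            combined = 2.0 / (1.0 / g + 1.0 / s)
            rows.append(
                {
                    "unit_id": unit,
                    "sex": sex,
                    "ggb": g,
                    "seg": s,
                    "combined": combined,
                    "truncated": min(combined, 1.0),
                    "fit_lo": fit_range[0],
                    "fit_hi": fit_range[1],
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def correct_deaths(deaths: DeathTable, coverage: pd.DataFrame, truncate: bool = True) -> DeathTable:
    """Inflate death counts by 1/coverage per unit x sex.

    ``coverage`` is the frame from :func:`estimate_coverage`; the
    ``truncated`` column is used unless ``truncate=False`` (sensitivity
    mode), in which case the raw ``combined`` value divides the counts even
    when it exceeds 1.
    """
    col = "truncated" if truncate else "combined"
    cov = coverage.set_index(["unit_id", "sex"])[col]
    strata = deaths.df[["unit_id", "sex"]].drop_duplicates()
    missing = [
        f"{r.unit_id}/{r.sex}"
        for r in strata.itertuples()
        if (r.unit_id, r.sex) not in cov.index
    ]
    if missing:
        raise ValidationError(f"no coverage estimate for {missing}")
    factors = deaths.df.set_index(["unit_id", "sex"]).index.map(cov)
    if (np.asarray(factors) <= 0).any():
        raise ValidationError("coverage must be positive")
    df = deaths.df.copy()
    df["deaths"] = df["deaths"] / np.asarray(factors, dtype=float)
    return DeathTable(df, deaths.scheme)
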