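"""End-to-end orchestration: ingest -> coverage -> correction -> smoothing
-> life tables -> inequality -> association, with a run manifest.

Sensitivity analyses are configuration modes, never separate code paths:
``undercount_mode`` switches between the main analysis (correct by
1/coverage truncated at 1), restricting to units with coverage >= 0.9
without correcting, and correcting without truncation; the outcome age
(0/40/60), the SES proxy (education/water/overcrowding) and the spatial
polynomial adjustment are plain config fields.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from lifegap.data_model import (
    AgeGroupScheme,
    DeathTable,
    PopulationTable,
    UnitAttributes,
    ValidationError,
    read_death_table,
    read_population_table,
    read_unit_attributes,
)
from lifegap.coverage import estimate_coverage, correct_deaths
from lifegap.smoothing import SmoothingConfig, fit_smoothing_model
from lifegap.lifetables import e0_draws, summarize_e0, DEFAULT_A0
from lifegap.inequality import inequality_summary, icc
from lifegap.association import RegressionSpec, association_pipeline

logger = logging.getLogger("lifegap")

UNDERCOUNT_MODES = ("correct", "drop_below_0.9", "no_truncation")


@dataclass
class PipelineConfig:
    deaths_path: str = "deaths.csv"
    population_path: str = "population.csv"
    units_path: str = "units.csv"
    outdir: str = "out"
    undercount_mode: str = "correct"
    coverage_fit_range: tuple = (15, 65)
    burn_in: int = 5000
    iterations: int = 20000
    n_draws: int = 2000
    chains: int = 2
    outcome_age: int = 0
    exposure: str = "education"
    spatial_adjust: bool = False
    a0: float = DEFAULT_A0
    extend_to: int = 105
    seed: int = 0

    def __post_init__(self):
        if self.undercount_mode not in UNDERCOUNT_MODES:
            raise ValidationError(f"undercount_mode must be one of {UNDERCOUNT_MODES}")


def _unit_seed(root: np.random.SeedSequence, key: str) -> int:
    h = zlib.crc32(key.encode()) % (2**20)
    return int(root.generate_state(1)[0] % 2**30) + h


def run_pipeline(config: PipelineConfig, tables=None) -> dict:
    """Run every stage and return (and write) the report bundle.

    ``tables`` may supply in-memory ``(DeathTable, PopulationTable,
    UnitAttributes)`` instead of the configured csv paths.  The bundle
    holds coverage, life_expectancy, inequality, icc, association frames
    and a manifest dict; each is also written under ``config.outdir``.
    """
    from pathlib import Path

    t_start = time.time()
    timings, warnings_log = {}, []

    if tables is None:
        scheme = AgeGroupScheme()
        deaths = read_death_table(config.deaths_path, scheme)
        population = read_population_table(config.population_path, scheme, deaths=deaths)
        attrs = read_unit_attributes(config.units_path)
    else:
        deaths, population, attrs = tables
    attrs = attrs.with_mean_population(population)
    city_of = dict(zip(attrs.df.unit_id, attrs.df.city_id))

    # --- coverage + correction -------------------------------------------
    t0 = time.time()
    coverage = estimate_coverage(
        deaths, population, fit_range=config.coverage_fit_range, city_of=city_of
    )
    if config.undercount_mode == "correct":
        corrected = correct_deaths(deaths, coverage, truncate=True)
    elif config.undercount_mode == "no_truncation":
        corrected = correct_deaths(deaths, coverage, truncate=False)
    else:  # drop_below_0.9: keep well-registered strata, uncorrected
        good = coverage[coverage.truncated >= 0.9][["unit_id", "sex"]]
        dropped = len(coverage) - len(good)
        if dropped:
            warnings_log.append(f"drop_below_0.9: excluded {dropped} unit x sex strata")
        kept = deaths.df.merge(good, on=["unit_id", "sex"])
        if kept.empty:
            raise ValidationError("drop_below_0.9 removed every stratum")
        corrected = DeathTable(kept, deaths.scheme)
    timings["coverage"] = time.time() - t0

    # --- smoothing + life tables per city x sex --------------------------
    t0 = time.time()
    root = np.random.SeedSequence(config.seed)
    le_rows, icc_rows, assoc_frames = [], [], []
    draws_by_sex: dict[str, list] = {}
    cities = sorted(attrs.df.city_id.unique())
    for city in cities:
        city_units = set(attrs.df.loc[attrs.df.city_id == city, "unit_id"])
        for sex in ("male", "female"):
            sub = corrected.df[(corrected.df.sex == sex) & corrected.df.unit_id.isin(city_units)]
            if sub.empty or sub.unit_id.nunique() < 2:
                warnings_log.append(f"{city}/{sex}: fewer than 2 units after filtering; skipped")
                continue
            d_cs = DeathTable(sub, corrected.scheme)
            smooth_cfg = SmoothingConfig(
                burn_in=config.burn_in,
                iterations=config.iterations,
                n_draws=config.n_draws,
                chains=config.chains,
                seed=_unit_seed(root, f"{city}|{sex}"),
            )
            draws = fit_smoothing_model(d_cs, population, smooth_cfg, sex=sex)
            if not draws.converged:
                warnings_log.append(f"{city}/{sex}: convergence gate failed {draws.diagnostics}")
            e_by_age = {
                age: e0_draws(draws, age=age, a0=config.a0, extend_to=config.extend_to)
                for age in (0, 40, 60)
            }
            s0 = summarize_e0(e_by_age[0])
            for _, r in s0.iterrows():
                le_rows.append(
                    {
                        "unit_id": r.unit_id,
                        "sex": sex,
                        "e0_median": r["median"],
                        "e0_lo95": r.lo95,
                        "e0_hi95": r.hi95,
                        "e40_median": e_by_age[40][r.unit_id].median(),
                        "e60_median": e_by_age[60][r.unit_id].median(),
                    }
                )
            draws_by_sex.setdefault(sex, []).append(e_by_age[config.outcome_age])
    timings["smoothing_lifetables"] = time.time() - t0

    life_expectancy = pd.DataFrame(le_rows)
    if life_expectancy.empty:
        raise ValidationError("no life expectancy estimates produced")

    # --- inequality + icc -------------------------------------------------
    t0 = time.time()
    outcome_col = {0: "e0_median", 40: "e40_median", 60: "e60_median"}[config.outcome_age]
    le_for_ineq = life_expectancy.rename(columns={outcome_col: "median"})[
        ["unit_id", "sex", "median"]
    ]
    ineq = inequality_summary(le_for_ineq, attrs)
    adf = attrs.df.set_index("unit_id")
    for sex, sub in le_for_ineq.groupby("sex"):
        labels = adf.loc[sub.unit_id, "city_id"].to_numpy()
        if len(np.unique(labels)) >= 2:
            res = icc(sub["median"].to_numpy(), labels)
            icc_rows.append({"sex": sex, "icc": res.icc, "flag": res.flag})
        else:
            icc_rows.append({"sex": sex, "icc": np.nan, "flag": "single_city"})
    icc_df = pd.DataFrame(icc_rows)
    timings["inequality"] = time.time() - t0

    # --- association -------------------------------------------------------
    t0 = time.time()
    spec = RegressionSpec(
        exposure=config.exposure,
        outcome_age=config.outcome_age,
        spatial_adjust=config.spatial_adjust,
    )
    assoc_cols = ["city_id", "sex", "exposure", "outcome_age", "coef", "se",
                  "lo95", "hi95", "m", "spatial_adjust"]
    for sex, frames in sorted(draws_by_sex.items()):
        e_all = pd.concat(frames, axis=1)
        a = association_pipeline(e_all, attrs, spec, on_small="skip")
        if len(a) < len(cities):
            warnings_log.append(f"{sex}: association skipped cities with < 4 units")
        if a.empty:
            continue
        a.insert(1, "sex", sex)
        assoc_frames.append(a)
    association = (
        pd.concat(assoc_frames, ignore_index=True)
        if assoc_frames
        else pd.DataFrame(columns=assoc_cols)
    )
    timings["association"] = time.time() - t0

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "n_units": int(attrs.df.shape[0]),
        "cities": cities,
        "warnings": warnings_log,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 2),
    }

    bundle = {
        "coverage": coverage,
        "life_expectancy": life_expectancy,
        "inequality": ineq,
        "icc": icc_df,
        "association": association,
        "manifest": manifest,
    }

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("coverage", "life_expectancy", "inequality", "icc", "association"):
        bundle[name].to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def make_table2(bundle: dict) -> pd.DataFrame:
    """Per-city summary in the layout of the headline results table.

    One row per city x sex: population-weighted mean life expectancy at
    birth across unit medians, the P90-P10 cell rendered as
    ``"p10 to p90 (gap)"`` at one decimal, and the pooled education
    coefficient with its 95% CI.
    """
    ineq = bundle["inequality"]
    assoc = bundle["association"]
    rows = []
    for _, iq in ineq.iterrows():
        city, sex = iq.city_id, iq.sex
        a = assoc[(assoc.city_id == city) & (assoc.sex == sex)]
        if a.empty:
            logger.warning("table2: no association row for %s/%s; omitted", city, sex)
            continue
        a = a.iloc[0]
        rows.append(
            {
                "city_id": city,
                "sex": sex,
                "mean_e0": round(float(iq.weighted_mean), 1),
                "p90_p10": f"{iq.p10:.1f} to {iq.p90:.1f} ({iq.gap:.1f})",
                "coef_ci": f"{a.coef:.1f} ({a.lo95:.1f} to {a.hi95:.1f})",
            }
        )
    return pd.DataFrame(rows)
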