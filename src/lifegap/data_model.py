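"""Core domain types and delimited-text I/O for the pipeline.

All tables are tidy (long-format) pandas DataFrames wrapped in light
container classes that validate their invariants on construction.  Age
groups are encoded by their integer lower bound in years; the last group
is open-ended (75+ by default).  Sex is one of ``{"male", "female"}`` and
no combined-sex stratum is ever synthesized: every analysis downstream is
sex-stratified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lifegap")

SEXES = ("male", "female")


class SchemaError(ValueError):
    """A required column is missing or has the wrong name."""


class ValidationError(ValueError):
    """A value violates a table invariant."""


@dataclass(frozen=True)
class AgeGroupScheme:
    """Abridged age grouping: 5-year groups from 0 with an open last group.

    Parameters
    ----------
    lower_bounds
        Strictly increasing integer lower bounds, starting at 0.  The last
        bound opens the terminal interval (e.g. 75 -> "75+").
    group_width
        Width in years of the closed groups (5 for the standard scheme).
    """

    lower_bounds: tuple = tuple(range(0, 80, 5))
    group_width: int = 5

    def __post_init__(self):
        lb = self.lower_bounds
        if len(lb) < 2:
            raise ValidationError("need at least two age groups")
        if lb[0] != 0:
            raise ValidationError("first age-group lower bound must be 0")
        if any(nxt <= prev for prev, nxt in zip(lb, lb[1:])):
            raise ValidationError("age-group lower bounds must be strictly increasing")

    @property
    def open_lower(self) -> int:
        return self.lower_bounds[-1]

    @property
    def n_groups(self) -> int:
        return len(self.lower_bounds)

    def midpoints(self) -> np.ndarray:
        """Hazard-evaluation midpoints: lower + width/2; open group lower + width."""
        mids = np.asarray(self.lower_bounds, dtype=float) + self.group_width / 2.0
        mids[-1] = self.lower_bounds[-1] + self.group_width
        return mids

    def widths(self) -> np.ndarray:
        w = np.diff(np.asarray(self.lower_bounds, dtype=float))
        return np.append(w, np.inf)

    def contains(self, age_lower) -> np.ndarray:
        return np.isin(np.asarray(age_lower), self.lower_bounds)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def _sorted(df: pd.DataFrame, keys) -> pd.DataFrame:
    return df.sort_values(list(keys), kind="mergesort").reset_index(drop=True)


class _StratifiedCounts:
    """Shared machinery for death and population tables."""

    value_col: str = ""
    keys = ("unit_id", "sex", "age_lower", "year")

    def __init__(self, df: pd.DataFrame, scheme: AgeGroupScheme | None = None):
        scheme = scheme or AgeGroupScheme()
        _require_columns(df, list(self.keys) + [self.value_col], type(self).__name__)
        df = df[list(self.keys) + [self.value_col]].copy()
        df["unit_id"] = df["unit_id"].astype(str)
        df["sex"] = df["sex"].astype(str)
        df["age_lower"] = df["age_lower"].astype(int)
        df["year"] = df["year"].astype(int)
        df[self.value_col] = df[self.value_col].astype(float)
        self._validate(df, scheme)
        self.df = _sorted(df, self.keys)
        self.scheme = scheme

    def _validate(self, df: pd.DataFrame, scheme: AgeGroupScheme) -> None:
        bad = df[df[self.value_col] < 0]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValidationError(
                f"negative {self.value_col} for unit={row.unit_id} sex={row.sex} "
                f"age={row.age_lower} year={row.year}: {row[self.value_col]}"
            )
        if not np.isfinite(df[self.value_col]).all():
            raise ValidationError(f"non-finite {self.value_col} value present")
        unknown_age = ~scheme.contains(df["age_lower"].to_numpy())
        unknown_sex = ~df["sex"].isin(SEXES).to_numpy()
        if unknown_age.any() or unknown_sex.any():
            raise ValidationError("unknown age group or sex label in table")
        if df.duplicated(list(self.keys)).any():
            raise ValidationError("duplicate (unit, sex, age_group, year) stratum")
        years = np.sort(df["year"].unique())
        if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValidationError(f"years must form a contiguous window, got {years.tolist()}")

    # -- convenience -------------------------------------------------------
    @property
    def units(self):
        return sorted(self.df["unit_id"].unique())

    @property
    def years(self):
        return sorted(self.df["year"].unique())

    def pivot(self, unit_id: str, sex: str) -> pd.Series:
        """Counts summed over years, indexed by age_lower, for one unit x sex."""
        sub = self.df[(self.df.unit_id == unit_id) & (self.df.sex == sex)]
        out = sub.groupby("age_lower")[self.value_col].sum()
        return out.reindex(self.scheme.lower_bounds, fill_value=0.0)

    def matrix(self, sex: str, units=None) -> pd.DataFrame:
        """Units x age-group matrix of counts summed over years for one sex."""
        sub = self.df[self.df.sex == sex]
        mat = sub.pivot_table(
            index="unit_id", columns="age_lower", values=self.value_col, aggfunc="sum", fill_value=0.0
        )
        mat = mat.reindex(columns=self.scheme.lower_bounds, fill_value=0.0)
        if units is not None:
            mat = mat.reindex(units, fill_value=0.0)
        return mat

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def equals(self, other) -> bool:
        a = _sorted(self.df, self.keys)
        b = _sorted(other.df, self.keys)
        return a.shape == b.shape and bool(
            (a[list(self.keys)] == b[list(self.keys)]).all().all()
        ) and np.allclose(a[self.value_col], b[self.value_col])


class DeathTable(_StratifiedCounts):
    """Death counts by subcity unit x sex x 5-year age group x year.

    Counts are real-valued: the 1/coverage undercount correction produces
    non-integer deaths.
    """

    value_col = "deaths"


class PopulationTable(_StratifiedCounts):
    """Population counts with the same strata as :class:`DeathTable`.

    One extra trailing year beyond the death window is permitted so the
    first/last profiles can serve as the two time points of the
    death-distribution methods.
    """

    value_col = "population"


_PROPORTIONS = ("education", "water", "overcrowding", "builtup")
_UNIT_COLS = ("unit_id", "city_id", "education", "water", "overcrowding", "builtup", "lon", "lat")


@dataclass
class UnitAttributes:
    """Per-unit covariates: SES proportions, built-up fraction, centroid, city.

    ``mean_population`` (average population over the study window, used as
    the analysis weight) is attached downstream from the population table
    via :meth:`with_mean_population`.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        _require_columns(self.df, _UNIT_COLS, "UnitAttributes")
        df = self.df.copy()
        df["unit_id"] = df["unit_id"].astype(str)
        df["city_id"] = df["city_id"].astype(str)
        for c in _PROPORTIONS + ("lon", "lat"):
            df[c] = df[c].astype(float)
        for c in _PROPORTIONS:
            bad = df[(df[c] < 0) | (df[c] > 1) | ~np.isfinite(df[c])]
            if not bad.empty:
                raise ValidationError(
                    f"{c} outside [0,1] for unit {bad.iloc[0].unit_id}: {bad.iloc[0][c]}"
                )
        if df.duplicated("unit_id").any():
            raise ValidationError("duplicate unit_id in attributes")
        if "mean_population" in df.columns and (df["mean_population"] <= 0).any():
            raise ValidationError("mean_population must be positive")
        self.df = df.sort_values("unit_id", kind="mergesort").reset_index(drop=True)

    @property
    def units(self):
        return list(self.df["unit_id"])

    def with_mean_population(self, population: PopulationTable) -> "UnitAttributes":
        mp = (
            population.df.groupby(["unit_id", "year"])["population"].sum()
            .groupby("unit_id").mean().rename("mean_population")
        )
        df = self.df.drop(columns=["mean_population"], errors="ignore").merge(
            mp, on="unit_id", how="left"
        )
        if df["mean_population"].isna().any():
            missing = df.loc[df["mean_population"].isna(), "unit_id"].tolist()
            raise ValidationError(f"no population data for unit(s) {missing}")
        return UnitAttributes(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def equals(self, other) -> bool:
        cols = [c for c in self.df.columns if c in other.df.columns]
        a, b = self.df[cols], other.df[cols]
        if a.shape != b.shape:
            return False
        num = a.select_dtypes("number").columns
        return bool((a.drop(columns=num) == b.drop(columns=num)).all().all()) and np.allclose(
            a[num], b[num]
        )


def _read_counts(path, scheme, cls, drop_unknown=True):
    df = pd.read_csv(path)
    _require_columns(df, list(cls.keys) + [cls.value_col], str(path))
    scheme = scheme or AgeGroupScheme()
    keep = df["sex"].isin(SEXES) & df["age_lower"].isin(scheme.lower_bounds)
    dropped = int((~keep).sum())
    if dropped and drop_unknown:
        logger.warning("%s: dropped %d row(s) with unknown age group or sex", path, dropped)
        df = df[keep]
    return cls(df, scheme)


def read_death_table(path, scheme: AgeGroupScheme | None = None) -> DeathTable:
    """Read deaths.csv (unit_id, sex, age_lower, year, deaths).

    Rows whose age group is not in the scheme or whose sex label is not
    male/female are dropped with a logged count; negative deaths raise.
    """
    return _read_counts(path, scheme, DeathTable)


def read_population_table(
    path, scheme: AgeGroupScheme | None = None, deaths: DeathTable | None = None
) -> PopulationTable:
    """Read population.csv; optionally check support against a death table."""
    pop = _read_counts(path, scheme, PopulationTable)
    if deaths is not None:
        check_population_supports(deaths, pop)
    return pop


def check_population_supports(deaths: DeathTable, population: PopulationTable) -> None:
    """Every stratum with deaths must have positive population."""
    d = deaths.df[deaths.df.deaths > 0]
    merged = d.merge(population.df, on=list(DeathTable.keys), how="left")
    bad = merged[merged["population"].isna() | (merged["population"] <= 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"deaths without supporting population: unit={row.unit_id} sex={row.sex} "
            f"age={row.age_lower} year={row.year}"
        )


def read_unit_attributes(path) -> UnitAttributes:
    """Read units.csv (unit_id, city_id, education, water, overcrowding, builtup, lon, lat)."""
    return UnitAttributes(pd.read_csv(path))
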