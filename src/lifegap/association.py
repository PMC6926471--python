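"""SES-life expectancy regressions pooled over posterior draws.

Within each city, unit life expectancy is regressed on area socioeconomic
status by population-weighted least squares, adjusted for the built-up
fraction (and optionally a second-degree polynomial in the unit centroid
coordinates to absorb broad spatial trends).  The exposure is divided by
its weighted P90-P10 range within the city, so the coefficient reads as
the difference in life expectancy associated with moving from the first to
the ninth exposure decile.  The regression is repeated over the posterior
life-expectancy draws (2000 per unit) and the coefficients are pooled with
Rubin's rules, which propagate the estimation uncertainty of life
expectancy into the reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lifegap.data_model import UnitAttributes, ValidationError
from lifegap.inequality import weighted_quantile

EXPOSURES = ("education", "water", "overcrowding")
OUTCOME_AGES = (0, 40, 60)


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress: exposure proxy, outcome age, adjustments, weighting."""

    exposure: str = "education"
    outcome_age: int = 0
    adjust_builtup: bool = True
    spatial_adjust: bool = False
    robust: bool = False

    def __post_init__(self):
        if self.exposure not in EXPOSURES:
            raise ValidationError(f"exposure must be one of {EXPOSURES}")
        if self.outcome_age not in OUTCOME_AGES:
            raise ValidationError(f"outcome_age must be one of {OUTCOME_AGES}")


@dataclass
class PooledEstimate:
    """Rubin-pooled coefficient: total variance T = W + (1 + 1/m) B."""

    qbar: float
    W: float
    B: float
    T: float
    se: float
    ci95: tuple
    m: int
    df: float


def scale_exposure(values, weights) -> np.ndarray:
    """Divide the exposure by its weighted P90-P10 range."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValidationError("need >= 2 distinct exposure values")
    rng = weighted_quantile(x, weights, 0.9) - weighted_quantile(x, weights, 0.1)
    if rng <= 0:
        raise ValidationError("weighted P90-P10 exposure range is zero")
    return x / rng


def _design(exposure_scaled, builtup=None, lon=None, lat=None, spatial=False):
    cols = [np.ones_like(exposure_scaled), exposure_scaled]
    names = ["intercept", "exposure"]
    if builtup is not None:
        cols.append(np.asarray(builtup, dtype=float))
        names.append("builtup")
    if spatial:
        if lon is None or lat is None:
            raise ValidationError("spatial adjustment requires lon/lat")
        zlon = (lon - lon.mean()) / lon.std()
        zlat = (lat - lat.mean()) / lat.std()
        cols += [zlon, zlat, zlon**2, zlat**2, zlon * zlat]
        names += ["lon", "lat", "lon2", "lat2", "lonlat"]
    return np.column_stack(cols), names


def _wls(X, Y, w, names, robust=False):
    """Weighted least squares of each column of Y on X.

    Returns the exposure coefficient and its sampling variance, vectorised
    over the columns of Y (one per posterior draw).
    """
    n, p = X.shape
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} units to fit {p} coefficients")
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    cond = np.linalg.cond(XtWX)
    if cond > 1e10:
        corr = np.corrcoef(X[:, 1:].T)
        raise ValidationError(f"collinear design (columns {names[1:]}, corr=\n{np.round(corr, 3)})")
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (Xw.T @ Y)  # (p, m)
    resid = Y - X @ beta
    j = names.index("exposure")
    if robust:
        # HC0 sandwich, per draw
        var = np.empty(Y.shape[1])
        for d in range(Y.shape[1]):
            meat = X.T @ (X * (w**2 * resid[:, d] ** 2)[:, None])
            var[d] = (XtWX_inv @ meat @ XtWX_inv)[j, j]
    else:
        sigma2 = np.sum(w[:, None] * resid**2, axis=0) / (n - p)
        var = sigma2 * XtWX_inv[j, j]
    return beta[j], var


def fit_wls(y, exposure_scaled, weights, builtup=None, lon=None, lat=None,
            spatial: bool = False, robust: bool = False):
    """Population-weighted regression of one outcome draw on scaled SES.

    Returns ``(coefficient, variance)`` for the exposure term.
    """
    X, names = _design(np.asarray(exposure_scaled, float), builtup, lon, lat, spatial)
    Y = np.asarray(y, dtype=float).reshape(-1, 1)
    w = np.asarray(weights, dtype=float)
    coef, var = _wls(X, Y, w, names, robust)
    return float(coef[0]), float(var[0])


def rubin_pool(coefficients, variances) -> PooledEstimate:
    """Combine repeated estimates with Rubin's rules.

    Q̄ = mean coefficient, W = mean within-analysis variance, B = sample
    variance of the coefficients, T = W + (1 + 1/m) B; the 95% CI uses a t
    reference with df = (m-1) (1 + W / ((1 + 1/m) B))², collapsing to the
    normal when B = 0.
    """
    q = np.asarray(coefficients, dtype=float)
    v = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2 or len(v) != m:
        raise ValidationError("need m >= 2 matched coefficients and variances")
    qbar = float(q.mean())
    W = float(v.mean())
    B = float(q.var(ddof=1))
    T = W + (1 + 1 / m) * B
    se = np.sqrt(T)
    if B > 0:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        crit = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        crit = stats.norm.ppf(0.975)
    return PooledEstimate(
        qbar=qbar, W=W, B=B, T=T, se=float(se),
        ci95=(qbar - crit * se, qbar + crit * se), m=m, df=float(df),
    )


def association_pipeline(e_draws: pd.DataFrame, attrs: UnitAttributes,
                         spec: RegressionSpec | None = None,
                         on_small: str = "raise") -> pd.DataFrame:
    """Per-city Rubin-pooled SES coefficients from life-expectancy draws.

    ``e_draws`` is the (n_draws x units) frame from
    :func:`lifegap.lifetables.e0_draws` for one sex; units are matched to
    ``attrs`` (which must carry mean_population) and the regression is run
    separately within each city, once per draw, then pooled.  Cities with
    fewer than 4 units (intercept + exposure + built-up not estimable)
    raise, or are skipped with ``on_small="skip"``.
    """
    spec = spec or RegressionSpec()
    adf = attrs.df.set_index("unit_id")
    if "mean_population" not in adf.columns:
        raise ValidationError("attributes need mean_population (use with_mean_population)")
    rows = []
    for city, sub in adf.groupby("city_id"):
        units = [u for u in e_draws.columns if u in sub.index]
        if len(units) < 4:
            if on_small == "skip":
                continue
            raise ValidationError(f"city {city}: need >= 4 units with draws")
        sub = sub.loc[units]
        w = sub["mean_population"].to_numpy()
        xs = scale_exposure(sub[spec.exposure].to_numpy(), w)
        X, names = _design(
            xs,
            sub["builtup"].to_numpy() if spec.adjust_builtup else None,
            sub["lon"].to_numpy(),
            sub["lat"].to_numpy(),
            spec.spatial_adjust,
        )
        Y = e_draws[units].to_numpy().T  # (units, draws)
        coefs, variances = _wls(X, Y, w, names, spec.robust)
        pooled = rubin_pool(coefs, variances)
        rows.append(
            {
                "city_id": city,
                "exposure": spec.exposure,
                "outcome_age": spec.outcome_age,
                "coef": pooled.qbar,
                "se": pooled.se,
                "lo95": pooled.ci95[0],
                "hi95": pooled.ci95[1],
                "m": pooled.m,
                "spatial_adjust": spec.spatial_adjust,
            }
        )
    return pd.DataFrame(rows)
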