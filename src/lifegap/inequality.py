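"""Population-weighted inequality summaries of unit-level life expectancy.

All quantities treat the subcity units of a city as a finite population
weighted by average unit population: weighted quantiles use the
cumulative-weight midpoint rule (each unit's value sits at the midpoint of
its weight band, with linear interpolation between; at equal weights this
reduces to standard type-5 sample quantiles), the Gini coefficient is the
weighted relative mean absolute difference (population convention, no
sample correction), and the CV is the weighted SD over the weighted mean.
The variance decomposition of units nested in cities is a random-intercept
model fit by REML; the ICC is between-city variance over total variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lifegap.data_model import ValidationError


def _check(values, weights):
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("empty input")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0) or not np.isfinite(x).all():
        raise ValidationError("weights must be positive and values finite")
    return x, w


def weighted_quantile(values, weights, p: float) -> float:
    """Weighted quantile with cumulative-weight midpoint interpolation."""
    if not 0 < p < 1:
        raise ValidationError("p must be in (0, 1)")
    x, w = _check(values, weights)
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order]
    cum = np.cumsum(w)
    pos = (cum - w / 2.0) / cum[-1]
    return float(np.interp(p, pos, x))


def p90_p10_gap(values, weights=None):
    """(p10, p90, gap): spread of unit life expectancy within a city."""
    x, w = _check(values, weights)
    if x.size < 2:
        raise ValidationError("need at least 2 units for a P90-P10 gap")
    p10 = weighted_quantile(x, w, 0.1)
    p90 = weighted_quantile(x, w, 0.9)
    return p10, p90, p90 - p10


def gini(values, weights=None) -> float:
    """Weighted Gini coefficient (relative mean absolute difference / 2)."""
    x, w = _check(values, weights)
    if np.any(x < 0):
        raise ValidationError("Gini requires non-negative values")
    order = np.argsort(x, kind="mergesort")
    x, w = x[order], w[order]
    W = w.sum()
    mean = float(np.sum(w * x) / W)
    if mean == 0:
        raise ValidationError("Gini undefined for zero weighted mean")
    cum_w = np.concatenate([[0.0], np.cumsum(w)[:-1]])
    cum_wx = np.concatenate([[0.0], np.cumsum(w * x)[:-1]])
    # sum over ordered pairs i>j of w_i w_j (x_i - x_j), O(n log n)
    pair_sum = float(np.sum(w * (x * cum_w - cum_wx)))
    return pair_sum / (W**2 * mean)


def coefficient_of_variation(values, weights=None) -> float:
    """Weighted SD over weighted mean (population-variance convention)."""
    x, w = _check(values, weights)
    W = w.sum()
    mean = float(np.sum(w * x) / W)
    if mean <= 0:
        raise ValidationError("CV requires positive weighted mean")
    var = float(np.sum(w * (x - mean) ** 2) / W)
    return np.sqrt(var) / mean


@dataclass
class ICCResult:
    icc: float
    var_between: float
    var_within: float
    flag: str = "ok"


def icc(values, cities, weights=None, weighted: bool = False) -> ICCResult:
    """Intraclass correlation of units nested in cities.

    Unweighted (default): linear random-intercept model fit by REML
    (statsmodels MixedLM); ICC = var_between / (var_between + var_within).
    ``weighted=True`` uses a population-weighted ANOVA method-of-moments
    variance-components estimate instead (frequency-weighted REML is
    convention-dependent).  Singular/degenerate fits return ICC 0 with a
    flag rather than raising.
    """
    x = np.asarray(values, dtype=float)
    cities = np.asarray(cities)
    labels = pd.unique(cities)
    if len(labels) < 2 or min(np.sum(cities == c) for c in labels) < 2:
        raise ValidationError("need >= 2 cities with >= 2 units each")
    if not weighted:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(x, np.ones((len(x), 1)), groups=cities).fit(reml=True)
                vb = float(np.asarray(res.cov_re)[0, 0])
                vw = float(res.scale)
            except Exception:
                return ICCResult(0.0, 0.0, float(np.var(x)), flag="singular")
        if not np.isfinite(vb) or vb <= 0:
            return ICCResult(0.0, 0.0, vw, flag="singular")
        return ICCResult(vb / (vb + vw), vb, vw)
    # weighted one-way ANOVA method of moments (Searle, unbalanced design)
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    grand = np.sum(w * x) / W
    ssb = ssw = sum_wc2 = 0.0
    k = len(labels)
    for c in labels:
        sel = cities == c
        wc = w[sel].sum()
        mc = np.sum(w[sel] * x[sel]) / wc
        ssb += wc * (mc - grand) ** 2
        ssw += np.sum(w[sel] * (x[sel] - mc) ** 2)
        sum_wc2 += wc**2
    vw = ssw / max(W - k, 1e-12)
    vb = (ssb - (k - 1) * vw) / (W - sum_wc2 / W)
    if not np.isfinite(vb) or vb <= 0:
        return ICCResult(0.0, 0.0, vw, flag="singular")
    return ICCResult(vb / (vb + vw), vb, vw)


def inequality_summary(le: pd.DataFrame, attrs) -> pd.DataFrame:
    """Per city x sex P90-P10 gap, Gini and CV of unit life expectancy.

    ``le`` needs columns unit_id, sex, median; ``attrs`` a
    :class:`~lifegap.data_model.UnitAttributes` with mean_population.
    """
    adf = attrs.df.set_index("unit_id")
    rows = []
    for (sex,), sub in le.groupby(["sex"]):
        for city, csub in sub.groupby(adf.loc[sub.unit_id, "city_id"].to_numpy()):
            if len(csub) < 2:
                continue  # a one-unit city has no within-city spread
            w = adf.loc[csub.unit_id, "mean_population"].to_numpy()
            v = csub["median"].to_numpy()
            p10, p90, gap = p90_p10_gap(v, w)
            rows.append(
                {
                    "city_id": city,
                    "sex": sex,
                    "weighted_mean": float(np.sum(w * v) / w.sum()),
                    "p10": p10,
                    "p90": p90,
                    "gap": gap,
                    "gini": gini(v, w),
                    "cv": coefficient_of_variation(v, w),
                    "n_units": len(v),
                }
            )
    return pd.DataFrame(rows).sort_values(["sex", "city_id"]).reset_index(drop=True)
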