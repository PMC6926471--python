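import numpy as np
import pandas as pd
import pytest

from lifegap.association import (
    RegressionSpec,
    association_pipeline,
    fit_wls,
    rubin_pool,
    scale_exposure,
)
from lifegap.data_model import UnitAttributes, ValidationError
from lifegap.inequality import weighted_quantile


def _attrs(n, rng, city="c1"):
    df = pd.DataFrame(
        {
            "unit_id": [f"{city}_u{i}" for i in range(n)],
            "city_id": city,
            "education": rng.beta(4, 6, n),
            "water": rng.uniform(0.2, 0.9, n),
            "overcrowding": rng.uniform(0.05, 0.5, n),
            "builtup": rng.beta(5, 2, n),
            "lon": rng.uniform(-59, -58, n),
            "lat": rng.uniform(-35, -34, n),
            "mean_population": rng.uniform(5e3, 5e4, n),
        }
    )
    return UnitAttributes(df)


class TestScaleExposure:
    def test_linearity_of_coefficient(self, rng):
        x = rng.beta(4, 6, 30)
        w = rng.uniform(1, 10, 30)
        rng_range = weighted_quantile(x, w, 0.9) - weighted_quantile(x, w, 0.1)
        xs = scale_exposure(x, w)
        assert np.allclose(xs * rng_range, x)

    def test_idempotence(self, rng):
        x = rng.beta(4, 6, 30)
        w = rng.uniform(1, 10, 30)
        xs = scale_exposure(x, w)
        assert weighted_quantile(xs, w, 0.9) - weighted_quantile(xs, w, 0.1) == pytest.approx(1.0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValidationError):
            scale_exposure([0.4, 0.4, 0.4], [1, 1, 1])


class TestWLS:
    def test_exact_linear_input_recovered(self, rng):
        n = 20
        xs = scale_exposure(rng.beta(4, 6, n), np.ones(n))
        builtup = rng.beta(5, 2, n)
        y = 3.0 * xs + 0.5 * builtup + 1.0
        coef, var = fit_wls(y, xs, rng.uniform(1, 10, n), builtup=builtup)
        assert coef == pytest.approx(3.0, abs=1e-10)
        assert var == pytest.approx(0.0, abs=1e-16)

    def test_integer_weights_equal_row_duplication(self, rng):
        n = 8
        xs = rng.normal(0, 1, n)
        y = 2.0 * xs + rng.normal(0, 0.5, n)
        w = rng.integers(1, 5, n).astype(float)
        coef_w, _ = fit_wls(y, xs, w)
        rep = np.repeat(np.arange(n), w.astype(int))
        coef_dup, _ = fit_wls(y[rep], xs[rep], np.ones(len(rep)))
        assert coef_w == pytest.approx(coef_dup, rel=1e-10)

    def test_permutation_invariance(self, rng):
        n = 15
        xs, y, w = rng.normal(size=n), rng.normal(size=n), rng.uniform(1, 5, n)
        p = rng.permutation(n)
        assert fit_wls(y, xs, w)[0] == pytest.approx(fit_wls(y[p], xs[p], w[p])[0])

    def test_collinear_design_rejected(self, rng):
        n = 10
        xs = rng.normal(size=n)
        with pytest.raises(ValidationError, match="collinear"):
            fit_wls(rng.normal(size=n), xs, np.ones(n), builtup=2 * xs)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        n = 25
        xs = rng.normal(size=n)
        b = rng.beta(5, 2, n)
        y = 1 + 2 * xs + 0.3 * b + rng.normal(0, 1, n)
        w = rng.uniform(1, 10, n)
        coef, var = fit_wls(y, xs, w, builtup=b)
        X = sm.add_constant(np.column_stack([xs, b]))
        res = sm.WLS(y, X, weights=w).fit()
        assert coef == pytest.approx(res.params[1], rel=1e-9)
        assert var == pytest.approx(res.bse[1] ** 2, rel=1e-9)


class TestRubinPool:
    def test_identical_draws(self):
        p = rubin_pool([2.0, 2.0, 2.0], [0.5, 0.5, 0.5])
        assert p.qbar == 2.0 and p.B == 0.0 and p.T == pytest.approx(0.5)
        assert p.ci95[0] < 2.0 < p.ci95[1]

    def test_hand_computed_example(self):
        p = rubin_pool([1.0, 2.0, 3.0], [0.25, 0.25, 0.25])
        assert p.qbar == pytest.approx(2.0)
        assert p.W == pytest.approx(0.25)
        assert p.B == pytest.approx(1.0)
        assert p.T == pytest.approx(0.25 + (4 / 3) * 1.0)
        assert p.se == pytest.approx(np.sqrt(1.58333333), abs=1e-4)

    def test_pooled_interval_wider_than_single_draw(self, rng):
        coefs = rng.normal(3.0, 1.0, 50)
        vars_ = np.full(50, 0.2)
        p = rubin_pool(coefs, vars_)
        single_width = 2 * 1.96 * np.sqrt(0.2)
        assert (p.ci95[1] - p.ci95[0]) > single_width

    def test_order_invariance(self, rng):
        coefs = rng.normal(0, 1, 30)
        vars_ = rng.uniform(0.1, 0.5, 30)
        p1 = rubin_pool(coefs, vars_)
        idx = rng.permutation(30)
        p2 = rubin_pool(coefs[idx], vars_[idx])
        assert p1.T == pytest.approx(p2.T) and p1.qbar == pytest.approx(p2.qbar)

    def test_single_draw_rejected(self):
        with pytest.raises(ValidationError):
            rubin_pool([1.0], [0.1])


class TestAssociationPipeline:
    def _draws_from_truth(self, attrs, beta, rng, m=50, noise=0.3):
        adf = attrs.df
        w = adf.mean_population.to_numpy()
        xs = scale_exposure(adf.education.to_numpy(), w)
        mu = 75.0 + beta * xs + 0.5 * adf.builtup.to_numpy()
        draws = mu[None, :] + rng.normal(0, noise, (m, len(mu)))
        return pd.DataFrame(draws, columns=adf.unit_id)

    def test_duplicated_draw_equals_single_fit(self, rng):
        attrs = _attrs(12, rng)
        e = self._draws_from_truth(attrs, 4.0, rng, m=1, noise=0.2)
        e5 = pd.concat([e] * 5, ignore_index=True)
        out = association_pipeline(e5, attrs)
        adf = attrs.df
        w = adf.mean_population.to_numpy()
        xs = scale_exposure(adf.education.to_numpy(), w)
        coef, _ = fit_wls(e.iloc[0].to_numpy(), xs, w, builtup=adf.builtup.to_numpy())
        assert out.coef.iloc[0] == pytest.approx(coef)

    def test_known_gradient_recovered(self, rng):
        attrs = _attrs(25, rng)
        e = self._draws_from_truth(attrs, 5.0, rng, m=100, noise=0.2)
        out = association_pipeline(e, attrs)
        assert out.coef.iloc[0] == pytest.approx(5.0, abs=0.5)
        assert out.lo95.iloc[0] < 5.0 < out.hi95.iloc[0]

    def test_qbar_equals_fit_on_mean_outcome(self, rng):
        """Linearity: pooled coefficient = coefficient of draw-averaged outcome."""
        attrs = _attrs(15, rng)
        e = self._draws_from_truth(attrs, 2.0, rng, m=40)
        out = association_pipeline(e, attrs)
        adf = attrs.df
        w = adf.mean_population.to_numpy()
        xs = scale_exposure(adf.education.to_numpy(), w)
        coef_mean, _ = fit_wls(e.mean(0).to_numpy(), xs, w, builtup=adf.builtup.to_numpy())
        assert out.coef.iloc[0] == pytest.approx(coef_mean, rel=1e-9)

    def test_spatial_adjustment_stable_when_coordinates_independent(self, rng):
        attrs = _attrs(40, rng)
        e = self._draws_from_truth(attrs, 3.0, rng, m=60, noise=0.2)
        plain = association_pipeline(e, attrs, RegressionSpec(spatial_adjust=False))
        spatial = association_pipeline(e, attrs, RegressionSpec(spatial_adjust=True))
        assert spatial.coef.iloc[0] == pytest.approx(plain.coef.iloc[0], abs=0.5)

    def test_multi_city_rows(self, rng):
        a1, a2 = _attrs(10, rng, "c1"), _attrs(10, rng, "c2")
        attrs = UnitAttributes(pd.concat([a1.df, a2.df], ignore_index=True))
        e = self._draws_from_truth(attrs, 3.0, rng, m=20)
        out = association_pipeline(e, attrs)
        assert sorted(out.city_id) == ["c1", "c2"]
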