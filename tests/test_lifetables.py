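import numpy as np
import pytest

from lifegap.data_model import AgeGroupScheme, ValidationError
from lifegap.lifetables import (
    RADIX,
    build_life_table,
    e0_draws,
    expectancy_from_rates,
    extended_scheme,
    extrapolate_rates,
    fit_gompertz,
    life_expectancy_at,
    summarize_e0,
)


def gompertz_rates(A, B, scheme):
    return A * np.exp(B * scheme.midpoints())


class TestGompertzFit:
    def test_exact_schedule_recovered(self, scheme):
        A0, B0 = 4e-5, 0.095
        fit = fit_gompertz(gompertz_rates(A0, B0, scheme), scheme)
        assert fit.A == pytest.approx(A0, rel=1e-10)
        assert fit.B == pytest.approx(B0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_rates_give_zero_slope(self, scheme):
        fit = fit_gompertz(np.full(scheme.n_groups, 0.01), scheme)
        assert fit.B == pytest.approx(0.0, abs=1e-12)
        assert fit.A == pytest.approx(0.01)

    def test_matches_grid_search_on_noisy_schedule(self, scheme, rng):
        """OLS solution beats/equals every point of a brute-force grid."""
        rates = gompertz_rates(5e-5, 0.09, scheme) * np.exp(rng.normal(0, 0.1, scheme.n_groups))
        fit = fit_gompertz(rates, scheme)
        mask = (np.array(scheme.lower_bounds) >= 45) & (np.array(scheme.lower_bounds) <= 70)
        mids, logr = scheme.midpoints()[mask], np.log(rates[mask])

        def sse(logA, B):
            return float(((logr - (logA + B * mids)) ** 2).sum())

        best = min(
            (sse(la, b), la, b)
            for la in np.linspace(np.log(fit.A) - 0.5, np.log(fit.A) + 0.5, 81)
            for b in np.linspace(fit.B - 0.02, fit.B + 0.02, 81)
        )
        assert sse(np.log(fit.A), fit.B) <= best[0] + 1e-12

    def test_nonpositive_rate_in_range_rejected(self, scheme):
        rates = gompertz_rates(5e-5, 0.09, scheme)
        rates[10] = 0.0  # age 50-54
        with pytest.raises(ValidationError):
            fit_gompertz(rates, scheme)


class TestExtrapolation:
    def test_exact_gompertz_everywhere(self, scheme):
        A0, B0 = 4e-5, 0.095
        rates = gompertz_rates(A0, B0, scheme)
        fit = fit_gompertz(rates, scheme)
        ext, ext_scheme = extrapolate_rates(rates, fit, scheme)
        assert ext_scheme.lower_bounds[-1] == 105
        mids = np.asarray(ext_scheme.lower_bounds, float) + 2.5
        assert np.allclose(ext[scheme.n_groups - 1:], A0 * np.exp(B0 * mids[scheme.n_groups - 1:]))
        # observed closed groups untouched
        assert np.allclose(ext[: scheme.n_groups - 1], rates[:-1])

    def test_extension_monotone_when_b_positive(self, scheme, rng):
        rates = gompertz_rates(5e-5, 0.09, scheme) * np.exp(rng.normal(0, 0.05, scheme.n_groups))
        fit = fit_gompertz(rates, scheme)
        ext, _ = extrapolate_rates(rates, fit, scheme)
        tail = ext[scheme.n_groups - 1:]
        assert np.all(np.diff(tail) > 0)

    def test_e0_matches_gompertz_survival_integral(self, scheme):
        """Life table on the extended schedule vs closed-form survival curve."""
        A0, B0 = 5e-5, 0.09
        rates = gompertz_rates(A0, B0, scheme)
        e0_lt = float(expectancy_from_rates(rates, scheme, age=0))
        x = np.arange(0, 130, 0.01)
        S = np.exp(-(A0 / B0) * (np.exp(B0 * x) - 1))
        e0_int = float(S.sum() * 0.01)
        assert e0_lt == pytest.approx(e0_int, abs=0.2)


class TestLifeTable:
    def test_closed_form_open_interval_only(self):
        """No mortality below 75, open-interval m = 0.1: e0 = 75 + 1/m."""
        scheme = AgeGroupScheme()
        rates = np.zeros(scheme.n_groups)
        rates[-1] = 0.1
        table = build_life_table(rates, scheme)
        assert life_expectancy_at(table, 0) == pytest.approx(85.0)
        assert life_expectancy_at(table, 40) == pytest.approx(45.0)

    def test_doubling_rates_decreases_e0(self, scheme, rng):
        rates = gompertz_rates(5e-5, 0.09, scheme)
        sch = extended_scheme(scheme)
        fit = fit_gompertz(rates, scheme)
        ext, _ = extrapolate_rates(rates, fit, scheme)
        e1 = life_expectancy_at(build_life_table(ext, sch), 0)
        e2 = life_expectancy_at(build_life_table(2 * ext, sch), 0)
        assert e2 < e1

    def test_conservation_identities(self, scheme):
        rates = gompertz_rates(5e-5, 0.09, scheme)
        fit = fit_gompertz(rates, scheme)
        ext, sch = extrapolate_rates(rates, fit, scheme)
        t = build_life_table(ext, sch)
        assert t.d.sum() == pytest.approx(RADIX)
        assert t.T[0] == pytest.approx(t.L.sum())
        assert np.all(np.diff(t.l) <= 0) and np.all(np.diff(t.T) <= 0)
        assert t.l[0] == RADIX

    def test_open_interval_zero_rate_rejected(self, scheme):
        rates = np.full(scheme.n_groups, 0.01)
        rates[-1] = 0.0
        with pytest.raises(ValidationError):
            build_life_table(rates, scheme)

    def test_constant_hazard_limit(self):
        """Single constant hazard, open interval dominating: e0 -> 1/mu."""
        scheme = AgeGroupScheme((0, 5))
        mu = 0.5
        table = build_life_table(np.array([mu, mu]), scheme, a0=2.5)
        # exact constant-hazard expectancy is 1/mu = 2; abridged approximation
        assert life_expectancy_at(table, 0) == pytest.approx(1 / mu, rel=0.05)

    def test_e0_invariant_to_radix(self, scheme, monkeypatch):
        rates = gompertz_rates(5e-5, 0.09, scheme)
        e_ref = float(expectancy_from_rates(rates, scheme))
        import lifegap.lifetables as lt

        monkeypatch.setattr(lt, "RADIX", 1.0)
        assert float(expectancy_from_rates(rates, scheme)) == pytest.approx(e_ref)

    def test_nonboundary_age_rejected(self, scheme):
        rates = np.full(scheme.n_groups, 0.01)
        table = build_life_table(rates, scheme)
        with pytest.raises(ValidationError):
            life_expectancy_at(table, 42)


class TestE0Draws:
    def test_identical_draws_give_identical_e0(self, scheme):
        class Draws:
            values = np.tile(gompertz_rates(5e-5, 0.09, scheme), (10, 3, 1))
            units = ["a", "b", "c"]

        Draws.scheme = scheme
        e = e0_draws(Draws())
        assert e.shape == (10, 3)
        assert float(e.stack().std()) == pytest.approx(0.0, abs=1e-9)
        s = summarize_e0(e)
        assert np.allclose(s["median"], e.iloc[0, 0])
        assert np.allclose(s.hi95 - s.lo95, 0.0)

    def test_vectorised_path_matches_scalar_pipeline(self, male_fit):
        """e0_draws equals fit->extrapolate->table run draw by draw."""
        e = e0_draws(male_fit)
        d, u = 7, 2
        rates = male_fit.values[d, u]
        scheme = male_fit.scheme
        fit = fit_gompertz(rates, scheme)
        ext, sch = extrapolate_rates(rates, fit, scheme)
        expected = life_expectancy_at(build_life_table(ext, sch), 0)
        assert e.iloc[d, u] == pytest.approx(expected, rel=1e-12)

    def test_median_e0_near_truth_for_well_observed_city(self, male_fit, city_bundle):
        s = summarize_e0(e0_draws(male_fit)).set_index("unit_id")
        truth = city_bundle["truth"]
        t = truth[truth.sex == "male"].set_index("unit_id")
        err = (s["median"] - t.true_e0).abs()
        assert err.mean() < 1.5
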