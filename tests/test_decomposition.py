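"""Nested OLS models, R² partition, increment F test, robust SEs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aqpd import (
    DailyDataset,
    decompose_variance,
    fit_nested_models,
    nested_anova_f,
    robust_se,
)
from aqpd.decomposition import ModelFit, _ols
from aqpd.phases import PhaseCalendar, PhaseInterval


def _calendar(names, sizes):
    phases, day = [], pd.Timestamp("2020-01-01")
    for name, k in zip(names, sizes):
        phases.append(PhaseInterval(name, day.date(), (day + pd.Timedelta(days=k - 1)).date()))
        day += pd.Timedelta(days=k)
    return PhaseCalendar(phases=phases, reference_phase=names[0])


def _daily(y, met: dict, phases, var="pm25"):
    n = len(y)
    frame = pd.DataFrame({"date": pd.date_range("2020-01-01", periods=n).date})
    frame[var] = y
    for k, v in met.items():
        frame[k] = v
    frame["phase"] = phases
    frame["weekday"] = True
    return DailyDataset(frame)


def _sim(seed, n=120, n_phases=3, signal=None):
    rng = np.random.default_rng(seed)
    sizes = [n // n_phases] * (n_phases - 1)
    sizes.append(n - sum(sizes))
    names = [f"P{i}" for i in range(n_phases)]
    cal = _calendar(names, sizes)
    phases = np.repeat(names, sizes)
    met = {v: rng.normal(size=n) for v in ("temp", "ws", "rh")}
    y = rng.normal(size=n)
    if signal is not None:
        y = y + signal(met, phases)
    return _daily(y, met, phases), cal


def _stub_fit(pollutant, tag, r2, k, n):
    """Minimal ModelFit carrying only what the partition arithmetic needs;
    RSS is on a unit-total-sum-of-squares scale."""
    idx = [f"b{i}" for i in range(k)]
    return ModelFit(
        pollutant=pollutant, tag=tag,
        params=pd.Series(np.zeros(k), index=idx),
        se=pd.Series(np.zeros(k), index=idx),
        r2=r2, rss=1.0 - r2, df_resid=n - k, n=n,
        vif=pd.Series(dtype=float), result=None,
    )


class TestFitNestedModels:
    def test_pure_noise_both_r2_small(self):
        daily, cal = _sim(0, n=300)
        m1, m2 = fit_nested_models(daily, "pm25", calendar=cal)
        assert m2.r2 < 0.1
        assert m1.r2 <= m2.r2

    def test_exact_linear_response_in_temperature(self):
        daily, cal = _sim(1, n=90)
        daily.frame["pm25"] = 2.0 + 3.0 * daily.frame["temp"]
        m1, m2 = fit_nested_models(daily, "pm25", calendar=cal)
        assert m1.r2 == pytest.approx(1.0, abs=1e-12)
        assert m2.r2 - m1.r2 == pytest.approx(0.0, abs=1e-12)

    def test_vif_near_one_for_orthogonal_predictors(self):
        daily, cal = _sim(2, n=4000)
        _, m2 = fit_nested_models(daily, "pm25", calendar=cal)
        met_vif = m2.vif[["temp", "ws", "rh"]]
        assert np.allclose(met_vif, 1.0, atol=0.05)

    def test_complete_case_rows_identical_between_models(self, default_daily, default_config):
        m1, m2 = fit_nested_models(default_daily, "so2", calendar=default_config.calendar)
        assert m1.n == m2.n

    def test_rank_deficiency_rejected_with_column_names(self):
        daily, cal = _sim(3, n=60)
        daily.frame["rh"] = daily.frame["temp"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="rank deficient"):
            fit_nested_models(daily, "pm25", calendar=cal, standardize=False)

    def test_null_increment_p_values_roughly_uniform(self):
        """Under a phase-free response the increment p-value is U(0,1):
        over 200 replicates the empirical CDF at 0.5 is near 0.5."""
        ps = []
        for seed in range(200):
            daily, cal = _sim(seed, n=60)
            m1, m2 = fit_nested_models(daily, "pm25", calendar=cal)
            ps.append(nested_anova_f(m1, m2)[2])
        ps = np.asarray(ps)
        assert abs((ps < 0.5).mean() - 0.5) < 0.1
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestNestedF:
    def test_identical_models_f_zero_p_one(self):
        m1 = _stub_fit("x", "M1", 0.25, 4, 100)
        m2 = _stub_fit("x", "M2", 0.25, 9, 100)
        f, _, p = nested_anova_f(m1, m2)
        assert f == 0.0 and p == 1.0

    def test_hand_built_rss_matches_closed_form(self):
        """12 rows, q=2 added indicators: F computed from raw RSS values
        by explicit arithmetic."""
        rss1, rss2, n, k2, q = 30.0, 18.0, 12, 6, 2
        m1 = _stub_fit("x", "M1", 1 - rss1, k2 - q, n)
        m1.rss = rss1
        m2 = _stub_fit("x", "M2", 1 - rss2, k2, n)
        m2.rss = rss2
        f, (df1, df2), p = nested_anova_f(m1, m2)
        expected = ((rss1 - rss2) / q) / (rss2 / (n - k2))
        assert f == pytest.approx(expected)
        assert (df1, df2) == (q, n - k2)
        assert p == pytest.approx(float(stats.f.sf(expected, q, n - k2)))

    def test_f_equals_squared_t_for_single_indicator(self):
        """With one added indicator the nested F equals the square of that
        coefficient's t statistic (algebraic identity)."""
        rng = np.random.default_rng(4)
        n = 50
        X1 = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n)})
        d = pd.Series(np.r_[np.zeros(n // 2), np.ones(n - n // 2)])
        X2 = X1.assign(ind=d)
        y = pd.Series(rng.normal(size=n) + 0.8 * d)
        m1 = _ols(y, X1, "x", "M1")
        m2 = _ols(y, X2, "x", "M2")
        f, _, _ = nested_anova_f(m1, m2)
        t = m2.params["ind"] / m2.se["ind"]
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_mismatched_rowsets_rejected(self):
        m1 = _stub_fit("x", "M1", 0.2, 4, 100)
        m2 = _stub_fit("x", "M2", 0.3, 9, 90)
        with pytest.raises(ValueError):
            nested_anova_f(m1, m2)


class TestDecomposeVariance:
    def test_published_o3_partition(self):
        """R²_full 0.812, R²_meteo 0.800 -> meteorology share 98.5%."""
        m1 = _stub_fit("o3", "M1", 0.800, 4, 271)
        m2 = _stub_fit("o3", "M2", 0.812, 9, 271)
        res = decompose_variance(m1, m2)
        assert round(res.pct_meteo, 1) == 98.5
        assert round(res.pct_covid, 1) == 1.5

    def test_equal_r2_gives_zero_covid_share(self):
        m1 = _stub_fit("x", "M1", 0.4, 4, 200)
        m2 = _stub_fit("x", "M2", 0.4, 9, 200)
        res = decompose_variance(m1, m2)
        assert res.pct_covid == 0.0 and res.pct_meteo == 100.0

    def test_shares_sum_to_100(self, default_daily, default_config):
        for pol in ("pm10", "pm25", "no2", "o3"):
            m1, m2 = fit_nested_models(default_daily, pol, calendar=default_config.calendar)
            res = decompose_variance(m1, m2)
            assert res.pct_meteo + res.pct_covid == pytest.approx(100.0, abs=1e-9)
            assert res.r2_covid >= 0.0

    def test_zero_r2_flagged(self):
        m1 = _stub_fit("x", "M1", 0.0, 4, 100)
        m2 = _stub_fit("x", "M2", 0.0, 9, 100)
        res = decompose_variance(m1, m2)
        assert res.flag == "r2-zero" and np.isnan(res.pct_meteo)

    def test_known_orthogonal_contributions_split_evenly(self):
        """Planted orthogonal meteorology and phase signals of equal
        variance split the explained component about 50/50."""
        splits = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            def signal(met, phases, rng=rng):
                eff = {"P0": -1.0, "P1": 0.0, "P2": 1.0}
                return met["temp"] * np.sqrt(2.0 / 3.0) + np.array([eff[p] for p in phases])
            daily, cal = _sim(seed, n=300, signal=signal)
            m1, m2 = fit_nested_models(daily, "pm25", calendar=cal)
            splits.append(decompose_variance(m1, m2).pct_meteo)
        assert abs(np.mean(splits) - 50.0) < 5.0


class TestRobustSE:
    def test_homoscedastic_robust_close_to_classical(self):
        daily, cal = _sim(10, n=600)
        _, m2 = fit_nested_models(daily, "pm25", calendar=cal)
        hc3 = robust_se(m2, "HC3")
        ratio = (hc3 / m2.se).to_numpy()
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_heteroscedastic_robust_larger_for_driving_term(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        y = pd.Series(x * rng.normal(size=n))  # Var(y|x) ∝ x²
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = _ols(y, X, "x", "M1")
        hc3 = robust_se(fit, "HC3")
        assert hc3["x"] > fit.se["x"] * 1.2

    def test_duplicated_rows_shrink_classical_se(self):
        """Duplicating every row leaves point estimates unchanged and
        shrinks classical SEs by about sqrt(2) (exactly sqrt((n-k)/(2n-k))
        times 1/sqrt(2) via the df correction)."""
        rng = np.random.default_rng(12)
        n, k = 200, 2
        x = rng.normal(size=n)
        y = pd.Series(1.0 + 2.0 * x + rng.normal(size=n))
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = _ols(y, X, "x", "M1")
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = pd.concat([y, y], ignore_index=True)
        fit2 = _ols(y2, X2, "x", "M1")
        assert np.allclose(fit2.params, fit.params, atol=1e-10)
        expected = np.sqrt(2.0 * (n - k) / (2 * n - k)) / np.sqrt(2.0)
        assert fit2.se["x"] / fit.se["x"] == pytest.approx(expected, rel=1e-6)
        assert fit2.se["x"] / fit.se["x"] == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_unknown_flavor_rejected(self):
        daily, cal = _sim(13, n=60)
        m1, _ = fit_nested_models(daily, "pm25", calendar=cal)
        with pytest.raises(ValueError):
            robust_se(m1, "HC9")
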