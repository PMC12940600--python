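"""Phase summaries, percent change, Kruskal-Wallis/Dunn/BH, Spearman,
guideline exceedances, weekday contrasts."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from aqpd import (
    DailyDataset,
    aggregate_daily,
    exceedance_frequency,
    generate_scenario,
    kruskal_dunn,
    percent_change,
    phase_summary,
    spearman_matrix,
    weekday_weekend_contrast,
)
from conftest import make_quiet_config


def _daily_from_groups(groups: dict[str, list], var="pm25") -> DailyDataset:
    rows, day = [], pd.Timestamp("2020-01-01")
    for phase, vals in groups.items():
        for v in vals:
            rows.append({"date": day.date(), "phase": phase, var: v,
                         "weekday": day.dayofweek < 5})
            day += pd.Timedelta(days=1)
    return DailyDataset(pd.DataFrame(rows))


class TestPhaseSummary:
    def test_basic_statistics(self):
        d = _daily_from_groups({"A": [1.0, 2.0, 3.0]})
        r = phase_summary(d, ["pm25"]).iloc[0]
        assert (r["mean"], r["sd"], r["median"]) == (2.0, 1.0, 2.0)
        assert (r["min"], r["max"], r["n"]) == (1.0, 3.0, 3)

    def test_single_value_has_undefined_sd(self):
        d = _daily_from_groups({"A": [5.0]})
        r = phase_summary(d, ["pm25"]).iloc[0]
        assert r["n"] == 1 and np.isnan(r["sd"])

    def test_zero_noise_scenario_reproduces_configured_phase_mean(self, quiet_daily):
        summ = phase_summary(quiet_daily, ["pm25"])
        m = summ.set_index("phase")["mean"]
        assert m["Phase 1"] == pytest.approx(16.91, abs=1e-9)


class TestPercentChange:
    def test_published_phase1_pm25_change(self, quiet_daily):
        """Phase-mean inputs 16.91 vs 12.60 give +34.2%."""
        pc = percent_change(quiet_daily, "Pre-Pandemic", ["pm25"])
        row = pc[pc.phase == "Phase 1"].iloc[0]
        assert round(row["pct_change"], 1) == 34.2
        assert row["abs_change"] == pytest.approx(4.31, abs=1e-9)

    def test_published_phase3_pm25_change(self, quiet_daily):
        pc = percent_change(quiet_daily, "Pre-Pandemic", ["pm25"])
        row = pc[pc.phase == "Phase 3"].iloc[0]
        assert round(row["pct_change"], 1) == -13.4

    def test_reference_phase_change_is_zero_with_symmetric_ci(self, default_daily):
        pc = percent_change(default_daily, "Pre-Pandemic", ["pm25"])
        ref = pc[pc.phase == "Pre-Pandemic"].iloc[0]
        assert ref["pct_change"] == 0.0
        assert ref["ci_low"] == pytest.approx(-ref["ci_high"])
        assert ref["ci_low"] <= 0.0 <= ref["ci_high"]

    def test_identical_means_ci_contains_zero(self):
        d = _daily_from_groups({"A": [10.0, 12.0, 14.0], "B": [14.0, 12.0, 10.0]})
        d.frame.loc[:, "phase"] = ["A"] * 3 + ["B"] * 3
        pc = percent_change(d, "A", ["pm25"])
        row = pc[pc.phase == "B"].iloc[0]
        assert row["pct_change"] == pytest.approx(0.0)
        assert row["ci_low"] < 0 < row["ci_high"]

    def test_zero_reference_mean_rejected(self):
        d = _daily_from_groups({"A": [0.0, 0.0], "B": [1.0, 2.0]})
        with pytest.raises(ValueError, match="zero"):
            percent_change(d, "A", ["pm25"])


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        d = _daily_from_groups({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [1.0, 2.0]})
        res = kruskal_dunn(d, "pm25")
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_h_without_ties(self):
        """Groups (1,2),(3,4),(5,6): pooled ranks 1..6, group mean ranks
        1.5/3.5/5.5, H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 = 32/7."""
        d = _daily_from_groups({"A": [1.0, 2.0], "B": [3.0, 4.0], "C": [5.0, 6.0]})
        res = kruskal_dunn(d, "pm25")
        assert res.h_statistic == pytest.approx(32.0 / 7.0)

    def test_bh_step_up_by_hand(self):
        """BH on (0.01, 0.02, 0.03): step-up gives (0.03, 0.03, 0.03)."""
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_pairs_present_with_bh_adjustment(self, default_daily):
        res = kruskal_dunn(default_daily, "pm25")
        assert len(res.pairwise) == 15  # C(6,2) phase pairs
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p"] - 1e-15).all()

    def test_separated_groups_significant(self):
        d = _daily_from_groups(
            {"A": [1.0, 1.1, 1.2, 0.9], "B": [5.0, 5.1, 4.9, 5.2], "C": [9.0, 9.1, 8.9, 9.2]}
        )
        res = kruskal_dunn(d, "pm25")
        assert res.p_value < 0.01


class TestSpearman:
    def _daily(self, cols):
        n = len(next(iter(cols.values())))
        frame = pd.DataFrame({"date": pd.date_range("2020-01-01", periods=n).date})
        for k, v in cols.items():
            frame[k] = v
        return DailyDataset(frame)

    def test_monotone_transform_gives_unit_rho(self):
        x = np.arange(1.0, 11.0)
        d = self._daily({"a": x, "b": x**3})
        rho = spearman_matrix(d, ["a", "b"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(1.0, 11.0)
        d = self._daily({"a": x, "b": -x})
        assert spearman_matrix(d, ["a", "b"]).loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        """x=(1,2,3,4), y=(2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6."""
        d = self._daily({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 1.0, 4.0, 3.0]})
        assert spearman_matrix(d, ["a", "b"]).loc["a", "b"] == pytest.approx(0.6)

    def test_symmetric_unit_diagonal(self, default_daily):
        rho = spearman_matrix(default_daily, ["pm25", "pm10", "temp", "ws"])
        assert np.allclose(rho, rho.T, equal_nan=True)
        assert np.allclose(np.diag(rho), 1.0)

    def test_too_few_pairs_flagged_missing(self):
        d = self._daily({"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, 1.0, 2.0, 3.0]})
        assert np.isnan(spearman_matrix(d, ["a", "b"]).loc["a", "b"])


class TestExceedance:
    def test_direct_count(self):
        d = _daily_from_groups({"A": [12.0, 16.0, 20.0]})
        res = exceedance_frequency(d, {"pm25": 15.0})
        r = res.iloc[0]
        assert (r["n_exceed"], r["n_valid"]) == (2, 3)
        assert r["fraction"] == pytest.approx(2 / 3)

    def test_exact_guideline_value_is_not_exceedance(self):
        d = _daily_from_groups({"A": [45.0, 45.0]}, var="pm10")
        res = exceedance_frequency(d, {"pm10": 45.0})
        assert res.iloc[0]["n_exceed"] == 0

    def test_zero_valid_days_fraction_undefined(self):
        d = _daily_from_groups({"A": [np.nan, np.nan]})
        res = exceedance_frequency(d, {"pm25": 15.0})
        assert np.isnan(res.iloc[0]["fraction"])

    def test_count_monotone_in_guideline(self, default_daily):
        counts = [
            exceedance_frequency(default_daily, {"pm25": g})["n_exceed"].sum()
            for g in (5.0, 10.0, 15.0, 25.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_o3_uses_8h_metric(self, default_daily):
        res = exceedance_frequency(default_daily)
        o3 = res[res.pollutant == "o3"]
        assert (o3["guideline"] == 100.0).all()


class TestWeekdayContrast:
    def test_no_uplift_contrast_near_zero(self):
        cfg = make_quiet_config(no2_weekday_uplift=0.0,
                                noise_sd={"no2": 0.5, "pm10": 0, "pm25": 0, "o3": 0,
                                          "so2": 0, "temp": 0, "ws": 0, "rh": 0,
                                          "pres": 0, "rad": 0})
        daily = aggregate_daily(generate_scenario(cfg), 18, cfg.calendar)
        res = weekday_weekend_contrast(daily, "no2")
        ok = res[res.flag == ""]
        assert ((ok["ci_low"] <= 0) & (0 <= ok["ci_high"])).mean() >= 0.8

    def test_uplift_on_zero_noise_data_matches_generator_arithmetic(self):
        """A centred 20% weekday multiplier on a 5 ug/m3 baseline separates
        weekday and weekend means by exactly uplift * baseline = 1.0."""
        cfg = make_quiet_config(no2_weekday_uplift=0.2)
        means = {p: dict(m) for p, m in cfg.phase_means.items()}
        means["no2"] = {ph: 5.0 for ph in means["no2"]}
        import dataclasses
        cfg = dataclasses.replace(cfg, phase_means=means)
        daily = aggregate_daily(generate_scenario(cfg), 18, cfg.calendar)
        res = weekday_weekend_contrast(daily, "no2")
        ok = res[res.flag == ""]
        assert np.allclose(ok["difference"], 0.2 * 5.0, atol=1e-9)

    def test_empty_stratum_flagged(self):
        d = _daily_from_groups({"A": [1.0, 2.0, 3.0]})
        d.frame["weekday"] = True
        res = weekday_weekend_contrast(d, "pm25")
        assert res.iloc[0]["flag"] == "insufficient-data"
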