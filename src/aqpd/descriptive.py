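"""Phase-stratified summaries, nonparametric contrasts, correlations,
guideline exceedances, and percent change versus the reference phase.

All statistics operate on QC-gated daily values. Group contrasts use the
Kruskal–Wallis omnibus test followed by Dunn's pairwise z tests on pooled
ranks with Benjamini–Hochberg adjustment; monotone association uses
Spearman's rank correlation with pairwise-complete deletion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import DailyDataset
from .scenario import POLLUTANTS

__all__ = [
    "WHO_2021_GUIDELINES",
    "phase_summary",
    "percent_change",
    "kruskal_dunn",
    "KruskalDunnResult",
    "spearman_matrix",
    "exceedance_frequency",
    "weekday_weekend_contrast",
]

#: WHO 2021 air-quality guideline levels, µg/m³ (24-h means; O3 as the
#: daily maximum 8-hour mean).
WHO_2021_GUIDELINES = {"pm10": 45.0, "pm25": 15.0, "no2": 25.0, "o3": 100.0, "so2": 40.0}


def _phase_order(daily: DailyDataset) -> list[str]:
    seen: list[str] = []
    for ph in daily.frame["phase"]:
        if ph not in seen:
            seen.append(ph)
    return seen


def phase_summary(daily: DailyDataset, pollutants: list[str] | None = None) -> pd.DataFrame:
    """Mean ± sd, median, range and n per pollutant × phase.

    Empty phases yield an n=0 record with missing statistics; single-day
    phases have an undefined (missing) sd.
    """
    if "phase" not in daily.frame.columns:
        raise ValueError("daily data has no phase labels")
    pollutants = pollutants or [p for p in POLLUTANTS if p in daily.frame.columns]
    rows = []
    for pol in pollutants:
        for ph in _phase_order(daily):
            vals = daily.phase_values(pol, ph)
            n = len(vals)
            rows.append(
                {
                    "pollutant": pol,
                    "phase": ph,
                    "n": n,
                    "mean": vals.mean() if n else np.nan,
                    "sd": vals.std(ddof=1) if n > 1 else np.nan,
                    "median": np.median(vals) if n else np.nan,
                    "min": vals.min() if n else np.nan,
                    "max": vals.max() if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def percent_change(
    daily: DailyDataset,
    reference_phase: str,
    pollutants: list[str] | None = None,
) -> pd.DataFrame:
    """Percent change of each phase mean versus the reference phase mean.

    Point estimate: (mean_i − mean_ref)/mean_ref × 100. The 95% CI is built
    on the difference scale, diff ± 1.96·sqrt(SE_i² + SE_ref²) with SEs of
    the mean, then divided by the reference mean.
    """
    summ = phase_summary(daily, pollutants)
    rows = []
    for pol, sub in summ.groupby("pollutant", sort=False):
        ref = sub[sub["phase"] == reference_phase]
        if ref.empty:
            raise KeyError(f"reference phase {reference_phase!r} not found")
        ref = ref.iloc[0]
        if not ref["n"] >= 2:
            raise ValueError(f"{pol}: reference phase needs n >= 2")
        if ref["mean"] == 0:
            raise ValueError(f"{pol}: reference mean is zero")
        se_ref = ref["sd"] / np.sqrt(ref["n"])
        for _, r in sub.iterrows():
            if r["n"] == 0 or np.isnan(r["mean"]):
                rows.append({"pollutant": pol, "phase": r["phase"], "abs_change": np.nan,
                             "pct_change": np.nan, "ci_low": np.nan, "ci_high": np.nan})
                continue
            diff = r["mean"] - ref["mean"]
            se_i = (r["sd"] / np.sqrt(r["n"])) if r["n"] > 1 else np.nan
            se_diff = np.sqrt(se_i**2 + se_ref**2)
            half = 1.96 * se_diff
            rows.append(
                {
                    "pollutant": pol,
                    "phase": r["phase"],
                    "abs_change": diff,
                    "pct_change": diff / ref["mean"] * 100.0,
                    "ci_low": (diff - half) / ref["mean"] * 100.0,
                    "ci_high": (diff + half) / ref["mean"] * 100.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class KruskalDunnResult:
    pollutant: str
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: phase_a, phase_b, z, p, p_adjusted


def kruskal_dunn(daily: DailyDataset, pollutant: str, alpha: float = 0.05) -> KruskalDunnResult:
    """Kruskal–Wallis omnibus test plus Dunn pairwise z tests with BH.

    Dunn's z uses the tie-corrected pooled-rank variance
    N(N+1)/12 − Σ(t³−t)/(12(N−1)); BH adjustment is applied across all
    phase pairs of the pollutant.
    """
    groups, names = [], []
    for ph in _phase_order(daily):
        vals = daily.phase_values(pollutant, ph)
        if len(vals) >= 2:
            groups.append(vals)
            names.append(ph)
    if len(groups) < 2:
        raise ValueError("need >=2 phases with >=2 observations each")

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)

    # Dunn on pooled mid-ranks
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    n_tot = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        ra, rb = rank_groups[i].mean(), rank_groups[j].mean()
        se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (ra - rb) / se if se > 0 else 0.0
        rows.append({"phase_a": a, "phase_b": b, "z": z,
                     "p": 2.0 * stats.norm.sf(abs(z))})
    pair = pd.DataFrame(rows)
    pair["p_adjusted"] = multipletests(pair["p"], alpha=alpha, method="fdr_bh")[1]
    return KruskalDunnResult(pollutant, float(h), float(p), pair)


def spearman_matrix(
    daily: DailyDataset, variables: list[str], min_pairs: int = 3
) -> pd.DataFrame:
    """Symmetric Spearman ρ matrix with pairwise-complete deletion.

    Cells with fewer than ``min_pairs`` complete pairs are missing.
    """
    sub = daily.frame[variables].astype(float)
    rho = sub.corr(method="spearman", min_periods=min_pairs)
    np.fill_diagonal(rho.values, 1.0)
    return rho


def exceedance_frequency(
    daily: DailyDataset, guidelines: dict[str, float] | None = None
) -> pd.DataFrame:
    """Days strictly above guideline per pollutant × phase.

    O3 is judged on the daily maximum 8-hour mean; all other pollutants on
    the 24-h daily mean. Fractions use valid days as denominator and are
    missing when a phase has no valid day.
    """
    guidelines = guidelines or WHO_2021_GUIDELINES
    for pol, g in guidelines.items():
        if not g > 0:
            raise ValueError(f"guideline for {pol!r} must be positive")
    rows = []
    for pol, g in guidelines.items():
        col = "o3_8h_max" if pol == "o3" and "o3_8h_max" in daily.frame.columns else pol
        if col not in daily.frame.columns:
            continue
        for ph in _phase_order(daily):
            vals = daily.phase_values(col, ph)
            n = len(vals)
            count = int((vals > g).sum())
            rows.append(
                {
                    "pollutant": pol,
                    "phase": ph,
                    "guideline": g,
                    "n_valid": n,
                    "n_exceed": count,
                    "fraction": count / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def weekday_weekend_contrast(daily: DailyDataset, pollutant: str) -> pd.DataFrame:
    """Per-phase weekday − weekend mean difference with a Welch 95% CI.

    Phases where either stratum has fewer than two valid days are flagged.
    """
    rows = []
    for ph in _phase_order(daily):
        sub = daily.frame[daily.frame["phase"] == ph]
        wd = sub.loc[sub["weekday"], pollutant].dropna().to_numpy()
        we = sub.loc[~sub["weekday"], pollutant].dropna().to_numpy()
        rec = {"phase": ph, "n_weekday": len(wd), "n_weekend": len(we)}
        if len(wd) < 2 or len(we) < 2:
            rec.update({"difference": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "flag": "insufficient-data"})
        else:
            diff = wd.mean() - we.mean()
            va, vb = wd.var(ddof=1) / len(wd), we.var(ddof=1) / len(we)
            se = np.sqrt(va + vb)
            if se > 0:
                df = (va + vb) ** 2 / (va**2 / (len(wd) - 1) + vb**2 / (len(we) - 1))
                half = stats.t.ppf(0.975, df) * se
            else:
                half = 0.0
            rec.update({"difference": diff, "ci_low": diff - half,
                        "ci_high": diff + half, "flag": ""})
        rows.append(rec)
    return pd.DataFrame(rows)
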