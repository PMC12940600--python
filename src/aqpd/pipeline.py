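"""End-to-end orchestration: input, QC, models, HIA, sensitivity variants.

A :class:`RunConfig` fully determines a run; identical config + seed gives
byte-identical outputs. The sensitivity suite re-runs the analysis along
the four robustness axes (completeness threshold 12/18/20, austral summer
and winter strata, 3-sd outlier exclusion, base vs extended meteorology)
and reports each variant's variance decomposition and HIA next to the base
run, never mutating it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import DailyDataset, HourlyDataset
from .decomposition import (
    DEFAULT_MET_VARS,
    EXTENDED_MET_VARS,
    decompose_variance,
    fit_nested_models,
)
from .descriptive import (
    exceedance_frequency,
    kruskal_dunn,
    percent_change,
    phase_summary,
)
from .forest import ForestSpec, compare_importance, fit_forest
from .health import HiaParams, beta_sensitivity, hia_table
from .io import read_hourly_csv, write_daily_csv, write_hourly_csv
from .phases import PhaseCalendar, default_ilo_calendar
from .qc import aggregate_daily
from .scenario import POLLUTANTS, ScenarioConfig, default_ilo_config
from .simulate import generate_scenario

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_full_analysis", "sensitivity_suite"]

SEASON_MONTHS = {"DJF": (12, 1, 2), "JJA": (6, 7, 8)}


class PipelineError(RuntimeError):
    """A stage failure; carries the failed stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run depends on.

    Exactly one of ``scenario`` / ``hourly_csv`` provides the input data.
    ``seed`` overrides the scenario, forest and Monte Carlo seeds so one
    integer reproduces the whole run.
    """

    scenario: ScenarioConfig | None = None
    hourly_csv: str | None = None
    calendar: PhaseCalendar = field(default_factory=default_ilo_calendar)
    min_valid_hours: int = 18
    met_set: str = "base"       # "base" | "extended"
    season: str = "all"         # "all" | "DJF" | "JJA"
    outlier_rule: str = "none"  # "none" | "3sd"
    hia: HiaParams = field(default_factory=HiaParams)
    forest: ForestSpec = field(default_factory=ForestSpec)
    include_forest: bool = True
    outdir: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 1 <= self.min_valid_hours <= 24:
            raise ValueError("min_valid_hours must be in 1..24")
        if self.met_set not in ("base", "extended"):
            raise ValueError("met_set must be 'base' or 'extended'")
        if self.season not in ("all", "DJF", "JJA"):
            raise ValueError("season must be 'all', 'DJF' or 'JJA'")
        if self.outlier_rule not in ("none", "3sd"):
            raise ValueError("outlier_rule must be 'none' or '3sd'")
        if self.scenario is None and self.hourly_csv is None:
            self.scenario = default_ilo_config()
        if self.seed is not None:
            if self.scenario is not None:
                self.scenario = dataclasses.replace(self.scenario, seed=self.seed)
            self.hia = dataclasses.replace(self.hia, mc_seed=self.seed)
            self.forest = dataclasses.replace(self.forest, seed=self.seed)

    @property
    def met_vars(self) -> tuple[str, ...]:
        return DEFAULT_MET_VARS if self.met_set == "base" else EXTENDED_MET_VARS

    def analysis_dict(self) -> dict:
        """Analysis-relevant options only (excludes output location)."""
        return {
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "hourly_csv": self.hourly_csv,
            "calendar": self.calendar.to_dict(),
            "min_valid_hours": self.min_valid_hours,
            "met_set": self.met_set,
            "season": self.season,
            "outlier_rule": self.outlier_rule,
            "hia": dataclasses.asdict(self.hia),
            "forest": dataclasses.asdict(self.forest),
            "include_forest": self.include_forest,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables of one run plus its provenance manifest."""

    summaries: pd.DataFrame
    percent_changes: pd.DataFrame
    exceedances: pd.DataFrame
    kruskal: pd.DataFrame
    decomposition: pd.DataFrame
    coefficients: pd.DataFrame
    importances: pd.DataFrame | None
    concordance: pd.DataFrame | None
    hia: pd.DataFrame
    hia_beta_sensitivity: pd.DataFrame
    manifest: dict
    daily: DailyDataset = field(repr=False, default=None)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "phase_summaries.csv": self.summaries,
            "percent_changes.csv": self.percent_changes,
            "exceedances.csv": self.exceedances,
            "kruskal_dunn.csv": self.kruskal,
            "decomposition.csv": self.decomposition,
            "coefficients.csv": self.coefficients,
            "hia.csv": self.hia,
            "hia_beta_sensitivity.csv": self.hia_beta_sensitivity,
        }
        if self.importances is not None:
            tables["importances.csv"] = self.importances
        if self.concordance is not None:
            tables["concordance.csv"] = self.concordance
        for name, tab in tables.items():
            if tab is not None:
                tab.to_csv(out / name, index=False)
        if self.daily is not None:
            write_daily_csv(self.daily, out / "daily.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _apply_season(daily: DailyDataset, season: str) -> DailyDataset:
    if season == "all":
        return daily
    months = SEASON_MONTHS[season]
    frame = daily.frame
    keep = pd.to_datetime(frame["date"]).dt.month.isin(months)
    return DailyDataset(frame[keep].reset_index(drop=True), daily.min_valid_hours)


def _apply_outlier_rule(daily: DailyDataset, rule: str) -> DailyDataset:
    """Exclude daily values beyond 3 sd of the full-period mean, per pollutant."""
    if rule == "none":
        return daily
    frame = daily.frame.copy()
    for pol in POLLUTANTS:
        if pol not in frame.columns:
            continue
        vals = frame[pol].astype(float)
        m, s = vals.mean(), vals.std(ddof=1)
        if np.isfinite(s) and s > 0:
            frame[pol] = vals.mask((vals - m).abs() > 3 * s)
    return DailyDataset(frame, daily.min_valid_hours)


def _coefficient_table(m1, m2) -> pd.DataFrame:
    rows = []
    for fit in (m1, m2):
        robust = fit.robust.get("HC3")
        for name in fit.params.index:
            rows.append(
                {
                    "pollutant": fit.pollutant,
                    "model": fit.tag,
                    "term": name,
                    "estimate": fit.params[name],
                    "se": fit.se[name],
                    "se_hc3": robust[name] if robust is not None else np.nan,
                    "vif": fit.vif.get(name, np.nan),
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run every analysis stage and assemble the report bundle.

    Any stage failure raises :class:`PipelineError` naming the stage; when
    an output directory is configured, tables computed before the failure
    are preserved on disk.
    """
    partial: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            if config.outdir:
                out = Path(config.outdir)
                out.mkdir(parents=True, exist_ok=True)
                for key, tab in partial.items():
                    if isinstance(tab, pd.DataFrame):
                        tab.to_csv(out / f"{key}.csv", index=False)
            raise PipelineError(name, exc) from exc

    hourly: HourlyDataset = stage(
        "input",
        lambda: generate_scenario(config.scenario)
        if config.scenario is not None
        else read_hourly_csv(config.hourly_csv),
    )
    daily = stage(
        "aggregate",
        lambda: aggregate_daily(hourly, config.min_valid_hours, config.calendar),
    )
    daily = stage("season-filter", lambda: _apply_season(daily, config.season))
    daily = stage("outlier-filter", lambda: _apply_outlier_rule(daily, config.outlier_rule))

    pollutants = [p for p in POLLUTANTS if p in daily.frame.columns]
    # seasonal strata may not cover the configured reference phase; fall
    # back to the earliest phase present in the (filtered) data
    present = set(daily.frame["phase"])
    ref = config.calendar.reference_phase
    if ref not in present:
        ref = next(p for p in config.calendar.names if p in present)

    partial["phase_summaries"] = summaries = stage(
        "descriptive", lambda: phase_summary(daily, pollutants)
    )
    partial["percent_changes"] = pchanges = stage(
        "percent-change", lambda: percent_change(daily, ref, pollutants)
    )
    partial["exceedances"] = exceed = stage(
        "exceedance", lambda: exceedance_frequency(daily)
    )

    skipped: dict[str, str] = {}

    def _kruskal():
        rows = []
        for pol in pollutants:
            try:
                res = kruskal_dunn(daily, pol)
            except ValueError as exc:
                skipped[f"kruskal/{pol}"] = str(exc)
                continue
            pair = res.pairwise.copy()
            pair.insert(0, "pollutant", pol)
            pair["h_statistic"] = res.h_statistic
            pair["h_p_value"] = res.p_value
            rows.append(pair)
        if not rows:
            raise ValueError("no pollutant had >=2 phases with >=2 observations")
        return pd.concat(rows, ignore_index=True)

    partial["kruskal_dunn"] = kw = stage("kruskal-dunn", _kruskal)

    def _decomp():
        dec_rows, coef_tabs, fits = [], [], {}
        for pol in pollutants:
            try:
                m1, m2 = fit_nested_models(
                    daily, pol, config.met_vars, config.calendar
                )
            except ValueError as exc:
                skipped[f"decomposition/{pol}"] = str(exc)
                continue
            dec_rows.append(decompose_variance(m1, m2).to_row())
            coef_tabs.append(_coefficient_table(m1, m2))
            fits[pol] = (m1, m2)
        if not dec_rows:
            raise ValueError("variance decomposition possible for no pollutant")
        return pd.DataFrame(dec_rows), pd.concat(coef_tabs, ignore_index=True), fits

    decomp_tab, coef_tab, fits = stage("decomposition", _decomp)
    partial["decomposition"] = decomp_tab
    partial["coefficients"] = coef_tab

    importances = concordance = None
    if config.include_forest:
        def _forest():
            imp_tabs, conc_rows = [], []
            for pol in fits:
                try:
                    imp = fit_forest(daily, pol, config.forest, config.calendar)
                except ValueError as exc:
                    skipped[f"forest/{pol}"] = str(exc)
                    continue
                tab = imp.table.copy()
                tab.insert(0, "pollutant", pol)
                tab["oob_mse"] = imp.oob_mse
                tab["oob_r2"] = imp.oob_r2
                imp_tabs.append(tab)
                m1, m2 = fits[pol]
                conc_rows.append(compare_importance(imp, decompose_variance(m1, m2)))
            if not imp_tabs:
                raise ValueError("forest possible for no pollutant")
            return pd.concat(imp_tabs, ignore_index=True), pd.DataFrame(conc_rows)

        importances, concordance = stage("forest", _forest)
        partial["importances"] = importances
        partial["concordance"] = concordance

    hia = stage("hia", lambda: hia_table(daily, ref, config.hia))
    partial["hia"] = hia
    hia_beta = stage(
        "hia-beta-sensitivity", lambda: beta_sensitivity(daily, ref, params=config.hia)
    )

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.analysis_dict(),
        "seed": config.seed,
        "versions": {
            "aqpd": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rows": {"hourly": len(hourly), "daily": len(daily)},
        "reference_phase": ref,
        "skipped": skipped,
    }

    bundle = ReportBundle(
        summaries=summaries, percent_changes=pchanges, exceedances=exceed,
        kruskal=kw, decomposition=decomp_tab, coefficients=coef_tab,
        importances=importances, concordance=concordance, hia=hia,
        hia_beta_sensitivity=hia_beta, manifest=manifest, daily=daily,
    )
    if config.outdir:
        bundle.write(config.outdir)
        if config.scenario is not None:
            write_hourly_csv(hourly, Path(config.outdir) / "hourly.csv")
    return bundle


def sensitivity_suite(config: RunConfig) -> dict[str, dict]:
    """Re-run the analysis along each robustness axis.

    Returns a mapping variant name → {'decomposition', 'hia', 'delta'} (or
    {'skipped': reason}); 'delta' is the variant-minus-base difference in
    each pollutant's %meteo share. The base run is never mutated.
    """
    base_cfg = dataclasses.replace(config, include_forest=False, outdir=None)
    base = run_full_analysis(base_cfg)
    base_pct = base.decomposition.set_index("pollutant")["pct_meteo"]

    variants: dict[str, RunConfig] = {}
    for thr in (12, 18, 20):
        variants[f"min_hours_{thr}"] = dataclasses.replace(base_cfg, min_valid_hours=thr)
    for season in ("DJF", "JJA"):
        variants[f"season_{season}"] = dataclasses.replace(base_cfg, season=season)
    variants["outliers_3sd"] = dataclasses.replace(base_cfg, outlier_rule="3sd")
    variants["met_extended"] = dataclasses.replace(base_cfg, met_set="extended")

    out: dict[str, dict] = {
        "base": {"decomposition": base.decomposition, "hia": base.hia,
                 "delta": base_pct - base_pct},
    }
    for name, vcfg in variants.items():
        try:
            res = run_full_analysis(vcfg)
        except PipelineError as err:
            out[name] = {"skipped": f"{err.stage}: {err.cause}"}
            continue
        pct = res.decomposition.set_index("pollutant")["pct_meteo"]
        out[name] = {
            "decomposition": res.decomposition,
            "hia": res.hia,
            "delta": (pct - base_pct).rename("delta_pct_meteo"),
        }
    return out
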