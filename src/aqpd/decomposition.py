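"""Nested-regression variance decomposition.

Two ordinary-least-squares models are fitted per pollutant on an identical
complete-case row set: a meteorology-only model (temperature, wind speed,
humidity, standardized) and a full model adding intervention-phase
indicators with the reference phase omitted. The full model's R² is
partitioned into the meteorology share (the reduced model's R²) and the
phase increment, and the increment is tested with the nested ANOVA F
statistic F = ((RSS₁−RSS₂)/q) / (RSS₂/df₂). Coefficient inference can use
heteroscedasticity-robust (sandwich) standard errors; the increment test
uses the classical RSS-based F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .datasets import DailyDataset
from .phases import PhaseCalendar
from .qc import standardize_predictors

__all__ = [
    "ModelFit",
    "DecompositionResult",
    "fit_nested_models",
    "decompose_variance",
    "nested_anova_f",
    "robust_se",
]

DEFAULT_MET_VARS = ("temp", "ws", "rh")
EXTENDED_MET_VARS = ("temp", "ws", "rh", "pres", "rad")


@dataclass
class ModelFit:
    """One fitted OLS model with the quantities decomposition needs."""

    pollutant: str
    tag: str  # "M1" (meteorology-only) or "M2" (full)
    params: pd.Series
    se: pd.Series
    r2: float
    rss: float
    df_resid: int
    n: int
    vif: pd.Series
    result: object = field(repr=False)  # statsmodels RegressionResults
    robust: dict[str, pd.Series] = field(default_factory=dict, repr=False)

    @property
    def n_coef(self) -> int:
        return len(self.params)


@dataclass
class DecompositionResult:
    """Per-pollutant R² partition between meteorology and phase indicators."""

    pollutant: str
    n: int
    r2_full: float
    r2_meteo: float
    r2_covid: float
    pct_meteo: float
    pct_covid: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    flag: str = ""

    def to_row(self) -> dict:
        return {
            "pollutant": self.pollutant, "n": self.n, "r2": self.r2_full,
            "r2_meteo": self.r2_meteo, "r2_covid": self.r2_covid,
            "pct_meteo": self.pct_meteo, "pct_covid": self.pct_covid,
            "f": self.f_statistic, "df1": self.df1, "df2": self.df2,
            "p": self.p_value, "flag": self.flag,
        }


def _phase_dummies(phase: pd.Series, calendar: PhaseCalendar) -> pd.DataFrame:
    order = [p for p in calendar.names if p in set(phase)]
    if not order:
        raise ValueError("no phase labels present")
    # fall back to the earliest present phase when the configured reference
    # is absent (seasonal strata may not cover it)
    ref = calendar.reference_phase if calendar.reference_phase in order else order[0]
    cats = pd.Categorical(phase, categories=[ref] + [p for p in order if p != ref])
    dummies = pd.get_dummies(cats, drop_first=True, dtype=float)
    dummies.columns = [f"phase[{c}]" for c in dummies.columns]
    dummies.index = phase.index
    return dummies


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept: list[str] = []
        for c in X.columns:
            cols = kept + [c]
            if np.linalg.matrix_rank(X[cols].to_numpy()) == len(kept):
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ols(y: pd.Series, X: pd.DataFrame, pollutant: str, tag: str) -> ModelFit:
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    vif_vals = {}
    non_const = [c for c in X.columns if c != "const"]
    if len(non_const) >= 2:
        for c in non_const:
            j = list(X.columns).index(c)
            vif_vals[c] = variance_inflation_factor(X.to_numpy(), j)
        high = {c: v for c, v in vif_vals.items() if v > 5}
        if high:
            warnings.warn(f"{pollutant}/{tag}: VIF > 5 for {sorted(high)}", stacklevel=2)
    elif non_const:
        vif_vals[non_const[0]] = 1.0
    return ModelFit(
        pollutant=pollutant, tag=tag, params=params, se=se,
        r2=float(res.rsquared), rss=float(res.ssr),
        df_resid=int(res.df_resid), n=int(res.nobs),
        vif=pd.Series(vif_vals), result=res,
    )


def fit_nested_models(
    daily: DailyDataset,
    pollutant: str,
    meteorology_vars: tuple[str, ...] = DEFAULT_MET_VARS,
    calendar: PhaseCalendar | None = None,
    standardize: bool = True,
) -> tuple[ModelFit, ModelFit]:
    """Fit the meteorology-only (M1) and full (M2) models for a pollutant.

    Both models are fitted on the identical complete-case row set (response,
    all meteorology variables, phase label) so their R² values are
    comparable. Meteorological predictors are standardized with constants
    from the full analysis window. Phase enters M2 as indicator columns
    with the calendar's reference phase as baseline.
    """
    frame = daily.frame
    if "phase" not in frame.columns:
        raise ValueError("daily data has no phase labels; pass a calendar to aggregate_daily")
    if calendar is None:
        raise ValueError("a PhaseCalendar is required to order phase indicators")

    if standardize:
        std_daily, _ = standardize_predictors(daily, list(meteorology_vars))
        frame = std_daily.frame

    cols = [pollutant, *meteorology_vars]
    cc = frame.dropna(subset=cols)
    dummies = _phase_dummies(cc["phase"], calendar)
    if dummies.shape[1] == 0:
        raise ValueError(f"{pollutant}: only one phase present; nothing to decompose")
    k = 1 + len(meteorology_vars) + dummies.shape[1]
    if len(cc) < 3 + k:
        raise ValueError(
            f"{pollutant}: only {len(cc)} complete-case rows for {k} coefficients"
        )

    y = cc[pollutant].astype(float)
    X1 = pd.DataFrame({"const": 1.0}, index=cc.index).join(
        cc[list(meteorology_vars)].astype(float)
    )
    X2 = X1.join(dummies)
    _check_rank(X2)

    m1 = _ols(y, X1, pollutant, "M1")
    m2 = _ols(y, X2, pollutant, "M2")
    for fit in (m1, m2):
        fit.robust["HC3"] = robust_se(fit, "HC3")
    return m1, m2


def robust_se(fit: ModelFit, flavor: str = "HC3") -> pd.Series:
    """Sandwich (heteroscedasticity-robust) coefficient SEs.

    HC3 rejects rows with leverage 1, for which its weighting is undefined.
    """
    flavor = flavor.upper()
    if flavor not in ("HC0", "HC1", "HC2", "HC3"):
        raise ValueError(f"unknown robust flavor {flavor!r}")
    res = fit.result
    if flavor in ("HC2", "HC3"):
        hat = res.get_influence().hat_matrix_diag
        bad = np.nonzero(np.isclose(hat, 1.0))[0]
        if bad.size:
            raise ValueError(f"leverage 1 at row index {bad[0]}; {flavor} undefined")
    cov = getattr(res, f"cov_{flavor}")
    return pd.Series(np.sqrt(np.diag(cov)), index=fit.params.index)


def nested_anova_f(m1: ModelFit, m2: ModelFit) -> tuple[float, tuple[int, int], float]:
    """Nested-model ANOVA F test for the added phase indicators.

    Returns (F, (q, df2), p) with F = ((RSS₁−RSS₂)/q)/(RSS₂/df₂).
    """
    if m1.n != m2.n:
        raise ValueError("models were fitted on different row sets")
    q = m2.n_coef - m1.n_coef
    if q < 1:
        raise ValueError("full model adds no regressors")
    df2 = m2.df_resid
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    f = ((m1.rss - m2.rss) / q) / (m2.rss / df2)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, q, df2))
    return float(f), (q, df2), p


def decompose_variance(m1: ModelFit, m2: ModelFit) -> DecompositionResult:
    """Partition the full model's R² into meteorology and phase shares.

    R²_covid = R²_full − R²_meteo (non-negative by nesting); the percentage
    shares are of the explained component and sum to 100 whenever the full
    model explains anything.
    """
    if m1.n != m2.n:
        raise ValueError("models were fitted on different row sets")
    if not set(m1.params.index) <= set(m2.params.index):
        raise ValueError("M1 predictors are not a subset of M2 predictors")
    r2_full, r2_meteo = m2.r2, m1.r2
    r2_covid = max(r2_full - r2_meteo, 0.0)
    flag = ""
    if r2_full > 0:
        pct_meteo = r2_meteo / r2_full * 100.0
        pct_covid = r2_covid / r2_full * 100.0
    else:
        pct_meteo = pct_covid = np.nan
        flag = "r2-zero"
    f, (q, df2), p = nested_anova_f(m1, m2)
    return DecompositionResult(
        pollutant=m2.pollutant, n=m2.n, r2_full=r2_full, r2_meteo=r2_meteo,
        r2_covid=r2_covid, pct_meteo=pct_meteo, pct_covid=pct_covid,
        f_statistic=f, df1=q, df2=df2, p_value=p, flag=flag,
    )
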