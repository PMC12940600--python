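"""Ensemble-of-regression-trees cross-check of the variance decomposition.

Bootstrap-aggregated regression trees are grown per pollutant on the same
predictors as the linear models (temperature, wind speed, humidity, and the
intervention phase as a categorical factor). Prediction skill is assessed
out-of-bag and variable importance is reported two ways: the permutation
measure (increase in out-of-bag MSE when a predictor is shuffled, averaged
over trees and scaled by the spread of the per-tree increases — the classic
%IncMSE convention) and the total impurity decrease from splits on each
predictor (IncNodePurity).

The bagging loop is explicit rather than delegated to a canned forest so
that each tree's out-of-bag rows are available for the per-tree permutation
importance. Phase is encoded as an ordinal code in chronological order:
because the phases are temporally ordered, threshold splits select
contiguous phase blocks, keeping the predictor count at p = 4 so the
default mtry = floor(p/3) = 1 applies as intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .datasets import DailyDataset
from .decomposition import DecompositionResult
from .phases import PhaseCalendar

__all__ = ["ForestSpec", "ImportanceTable", "fit_forest", "compare_importance"]


@dataclass
class ForestSpec:
    """Hyperparameters of the bagged-tree ensemble."""

    n_trees: int = 500
    m_try: int | None = None  # None -> max(1, floor(p/3))
    min_node_size: int = 5
    seed: int = 123
    predictors: tuple[str, ...] = ("temp", "ws", "rh", "phase")

    def resolve_mtry(self, p: int) -> int:
        m = self.m_try if self.m_try is not None else max(1, p // 3)
        if not 1 <= m <= p:
            raise ValueError(f"m_try must be in 1..{p}, got {m}")
        return m

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass
class ImportanceTable:
    """Per-predictor importance plus out-of-bag fit quality."""

    pollutant: str
    table: pd.DataFrame  # predictor, pct_inc_mse, raw_inc_mse, inc_node_purity
    oob_mse: float
    oob_r2: float
    spec: ForestSpec = field(repr=False, default=None)


def _node_purity_gains(tree: DecisionTreeRegressor, n_features: int) -> np.ndarray:
    """Total weighted impurity decrease per feature over a tree's splits."""
    t = tree.tree_
    gains = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n = t.weighted_n_node_samples
        dec = n[node] * t.impurity[node] - n[left] * t.impurity[left] - n[right] * t.impurity[right]
        gains[t.feature[node]] += dec
    return gains


def fit_forest(
    daily: DailyDataset,
    pollutant: str,
    spec: ForestSpec | None = None,
    calendar: PhaseCalendar | None = None,
) -> ImportanceTable:
    """Grow the bagged ensemble and compute OOB error and importances.

    Complete cases across the response and all predictors are required
    (at least 30 rows). Identical seeds give identical importances.
    """
    spec = spec or ForestSpec()
    frame = daily.frame
    met = [v for v in spec.predictors if v != "phase"]
    cols = [pollutant, *met] + (["phase"] if "phase" in spec.predictors else [])
    cc = frame.dropna(subset=cols)
    if len(cc) < 30:
        raise ValueError(f"{pollutant}: only {len(cc)} complete-case rows (need >= 30)")

    y = cc[pollutant].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError(f"{pollutant}: constant response")

    features = list(met)
    X_parts = [cc[met].to_numpy(dtype=float)]
    if "phase" in spec.predictors:
        order = calendar.names if calendar is not None else list(dict.fromkeys(cc["phase"]))
        codes = cc["phase"].map({ph: i for i, ph in enumerate(order)})
        if codes.isna().any():
            raise ValueError("phase label outside the calendar")
        X_parts.append(codes.to_numpy(dtype=float)[:, None])
        features.append("phase")
    X = np.hstack(X_parts)
    n, p = X.shape
    mtry = spec.resolve_mtry(p)

    rng = np.random.default_rng(spec.seed)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    diffs = np.full((spec.n_trees, p), np.nan)  # per-tree OOB MSE increases
    purity = np.zeros(p)

    for t in range(spec.n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=spec.min_node_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        purity += _node_purity_gains(tree, p)
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])
        oob_sum[oob] += pred
        oob_cnt[oob] += 1
        base_mse = np.mean((y[oob] - pred) ** 2)
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm_mse = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            diffs[t, j] = perm_mse - base_mse

    seen = oob_cnt > 0
    oob_pred = np.where(seen, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    oob_mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2))
    oob_r2 = float(1.0 - oob_mse / np.var(y[seen]))

    raw = np.nanmean(diffs, axis=0)
    sd = np.nanstd(diffs, axis=0, ddof=0)
    scaled = np.where(sd > np.finfo(float).eps, raw / np.where(sd > 0, sd, 1.0), raw)
    table = pd.DataFrame(
        {
            "predictor": features,
            "pct_inc_mse": scaled,
            "raw_inc_mse": raw,
            "inc_node_purity": purity,
        }
    )
    return ImportanceTable(pollutant=pollutant, table=table, oob_mse=oob_mse,
                           oob_r2=oob_r2, spec=spec)


def compare_importance(
    importance: ImportanceTable, decomposition: DecompositionResult
) -> dict:
    """Concordance of meteorology-vs-phase dominance across the two methods.

    The forest's meteorology share is the clipped raw permutation importance
    of the meteorological predictors over the combined total; it is compared
    in direction with the regression %meteo/%covid split. A vanishing total
    importance yields an 'indeterminate' verdict.
    """
    tab = importance.table.set_index("predictor")
    met_imp = float(tab.loc[tab.index != "phase", "raw_inc_mse"].clip(lower=0).sum())
    phase_imp = float(tab.loc["phase", "raw_inc_mse"]) if "phase" in tab.index else 0.0
    phase_imp = max(phase_imp, 0.0)
    total = met_imp + phase_imp

    out = {
        "pollutant": importance.pollutant,
        "forest_met_share": np.nan,
        "forest_phase_share": np.nan,
        "regression_pct_meteo": decomposition.pct_meteo,
        "regression_pct_covid": decomposition.pct_covid,
        "verdict": "indeterminate",
    }
    if total <= 0 or importance.oob_r2 <= 0 or not np.isfinite(decomposition.pct_meteo):
        return out
    met_share = met_imp / total * 100.0
    out["forest_met_share"] = met_share
    out["forest_phase_share"] = 100.0 - met_share
    forest_met_dominant = met_share > 50.0
    regression_met_dominant = decomposition.pct_meteo > 50.0
    out["verdict"] = "agree" if forest_met_dominant == regression_met_dominant else "disagree"
    return out
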