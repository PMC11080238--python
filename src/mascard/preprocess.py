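"""Missing-value imputation, derived range flags, outlier handling, Z-scoring.

The imputation is tiered: features missing less than ``low_threshold`` are
filled with the mode (binary) or mean (continuous); features between the
thresholds are filled by iterative random-forest imputation; features at or
above ``high_threshold`` are rejected so that dropping data stays an explicit
caller decision. A Mann-Whitney U audit compares each feature's observed
values before imputation with the completed vector afterwards, to confirm
imputation did not shift the distribution.

Standardization is a fitted model: the training cohort's per-feature mean and
SD are stored and reapplied unchanged to any later (e.g. external) cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .synth import CohortTable, FeatureSpec

__all__ = [
    "ImputationPolicy",
    "ScalerParams",
    "impute",
    "audit_shift",
    "derive_range_flags",
    "flag_outliers_iqr",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
]


@dataclass(frozen=True)
class ImputationPolicy:
    low_threshold: float = 0.05
    high_threshold: float = 0.20
    n_estimators: int = 100   # trees per random-forest imputation model
    max_iter: int = 10
    audit_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.low_threshold < self.high_threshold < 1.0:
            raise ValueError("require 0 < low_threshold < high_threshold < 1")


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, float)) <= {0.0, 1.0}


def impute(cohort: CohortTable, policy: ImputationPolicy = ImputationPolicy()
           ) -> tuple[CohortTable, dict[str, str]]:
    """Fill every missing entry; returns the completed cohort and a per-feature
    report of the method used ("complete", "mean", "mode", "random_forest").

    Raises ValueError naming any feature whose missing fraction reaches
    ``policy.high_threshold`` — such features must be dropped upstream.
    """
    frame = cohort.frame.copy()
    frac = frame.isna().mean()
    too_missing = frac[frac >= policy.high_threshold]
    if len(too_missing):
        raise ValueError(
            "missing fraction at/above high threshold for: "
            + ", ".join(f"{k} ({v:.1%})" for k, v in too_missing.items()))

    report: dict[str, str] = {}
    mid_cols: list[str] = []
    for name in frame.columns:
        f = frac[name]
        if f == 0:
            report[name] = "complete"
        elif f < policy.low_threshold:
            col = frame[name]
            if _is_binary(col):
                fill = float(col.mode().iloc[0])
                report[name] = "mode"
            else:
                fill = float(col.mean())
                report[name] = "mean"
            frame[name] = col.fillna(fill)
        else:
            mid_cols.append(name)
            report[name] = "random_forest"

    if mid_cols:
        imputer = IterativeImputer(
            estimator=RandomForestRegressor(
                n_estimators=policy.n_estimators, random_state=policy.seed),
            max_iter=policy.max_iter, random_state=policy.seed,
            sample_posterior=False, keep_empty_features=True)
        filled = imputer.fit_transform(frame.to_numpy(float))
        out = pd.DataFrame(filled, columns=frame.columns, index=frame.index)
        for name in mid_cols:
            if _is_binary(cohort.frame[name]):
                out[name] = (out[name] >= 0.5).astype(float)
        # iterative imputation must not touch features completed earlier
        out[[c for c in frame.columns if c not in mid_cols]] = \
            frame[[c for c in frame.columns if c not in mid_cols]]
        frame = out

    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy()), report


@dataclass
class ShiftAudit:
    p_values: dict[str, float]
    skipped: list[str]
    alpha: float

    @property
    def passed(self) -> bool:
        return all(p >= self.alpha for p in self.p_values.values())


def audit_shift(before: CohortTable, after: CohortTable, alpha: float = 0.05) -> ShiftAudit:
    """Mann-Whitney U test per imputed feature: observed values pre-imputation
    vs. the full completed vector. Features with < 2 observed values are
    skipped and flagged."""
    if list(before.frame.columns) != list(after.frame.columns):
        raise ValueError("before/after schema mismatch")
    p_values: dict[str, float] = {}
    skipped: list[str] = []
    for name in before.frame.columns:
        obs = before.frame[name].dropna().to_numpy(float)
        if not before.frame[name].isna().any():
            continue  # nothing was imputed
        if len(obs) < 2:
            skipped.append(name)
            continue
        full = after.frame[name].to_numpy(float)
        if np.all(obs == obs[0]) and np.all(full == obs[0]):
            p_values[name] = 1.0
            continue
        _, p = stats.mannwhitneyu(obs, full, alternative="two-sided")
        p_values[name] = float(p)
    return ShiftAudit(p_values, skipped, alpha)


def derive_range_flags(cohort: CohortTable, specs: list[FeatureSpec]) -> CohortTable:
    """Append one ternary ``<feature>_flag`` column per continuous feature:
    1 above the upper normal limit, −1 below the lower limit, 0 inside the
    (inclusive) reference interval. Original columns are retained."""
    frame = cohort.frame.copy()
    by_name = {s.name: s for s in specs}
    for name in cohort.frame.columns:
        spec = by_name.get(name)
        if spec is None or spec.kind != "continuous":
            continue
        if spec.normal_range is None:
            raise ValueError(f"feature {name!r} lacks a normal_range")
        lo, hi = spec.normal_range
        x = frame[name]
        flag = pd.Series(np.zeros(len(x)), index=x.index)
        flag[x > hi] = 1.0
        flag[x < lo] = -1.0
        flag[x.isna()] = np.nan
        frame[f"{name}_flag"] = flag
    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy())


def flag_outliers_iqr(cohort: CohortTable, k: float = 1.5,
                      columns: list[str] | None = None,
                      action: str = "winsorize"
                      ) -> tuple[pd.DataFrame, CohortTable]:
    """Box-plot outlier handling: entries outside [Q1 − k·IQR, Q3 + k·IQR]
    are flagged; the returned cohort either clips them to the fences
    (``action="winsorize"``, default) or blanks them (``action="remove"``).

    Binary and ternary flag columns are excluded unless listed explicitly.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if action not in ("winsorize", "remove"):
        raise ValueError(f"unknown action {action!r}")
    frame = cohort.frame.copy()
    if columns is None:
        columns = [c for c in frame.columns
                   if frame[c].dropna().nunique() > 3 and not c.endswith("_flag")]
    flags = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    for name in columns:
        x = frame[name]
        q1, q3 = np.nanpercentile(x.to_numpy(float), [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out = (x < lo) | (x > hi)
        flags[name] = out.fillna(False)
        if action == "winsorize":
            frame[name] = x.clip(lo, hi)
        else:
            frame.loc[out.fillna(False), name] = np.nan
    return flags, CohortTable(frame, cohort.label.copy(),
                              None if cohort.outcome is None else cohort.outcome.copy())


@dataclass
class ScalerParams:
    """Per-feature standardization parameters fitted on the training cohort."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean, "sd": self.sd}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScalerParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean=d["mean"], sd=d["sd"])


def zscore_fit(cohort: CohortTable, columns: list[str] | None = None) -> ScalerParams:
    """Estimate per-feature mean and (population) SD on the training cohort."""
    cols = columns if columns is not None else list(cohort.frame.columns)
    params = ScalerParams()
    for name in cols:
        x = cohort.frame[name].to_numpy(float)
        m, s = float(np.nanmean(x)), float(np.nanstd(x))
        if s == 0.0:
            raise ValueError(f"zero-variance feature {name!r} cannot be Z-scored")
        params.mean[name], params.sd[name] = m, s
    return params


def zscore_apply(cohort: CohortTable, params: ScalerParams) -> CohortTable:
    """Transform with stored training parameters; never re-estimates."""
    frame = cohort.frame.copy()
    for name, m in params.mean.items():
        frame[name] = (frame[name] - m) / params.sd[name]
    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy())


def zscore_invert(cohort: CohortTable, params: ScalerParams) -> CohortTable:
    frame = cohort.frame.copy()
    for name, m in params.mean.items():
        frame[name] = frame[name] * params.sd[name] + m
    return CohortTable(frame, cohort.label.copy(),
                       None if cohort.outcome is None else cohort.outcome.copy())
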