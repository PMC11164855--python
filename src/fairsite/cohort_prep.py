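"""Cohort construction and preprocessing.

Age-based case-control matching, stratified train/validation/test splits,
cross-site feature harmonisation, missingness-based feature exclusion, and
standardisation with population-median imputation. All preprocessing state
is fit on training rows only and applied unchanged to every other split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import feature_columns

__all__ = [
    "SplitPlan",
    "PreprocessState",
    "match_controls",
    "split_extract",
    "harmonize_features",
    "filter_missingness",
    "fit_preprocess",
    "impute_median",
    "apply_preprocess",
]


@dataclass(frozen=True)
class SplitPlan:
    """Label-stratified split fractions for (train, continuous_validation, test)."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def match_controls(
    positives: pd.DataFrame,
    controls: pd.DataFrame,
    ratio: int = 20,
    age_window: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Match each case to ``ratio`` label-certain controls of similar age.

    Controls are matched greedily (nearest age first, never reused), with
    cases processed in a seeded random order. With the default 20:1 ratio
    the output prevalence is exactly 1/21, emulating a ~5% training
    prevalence from a pool of pre-outbreak negative presentations.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    for name, table in (("positives", positives), ("controls", controls)):
        if "age" not in table.columns:
            raise ValueError(f"{name} table lacks the 'age' column required for matching")
    if ratio == 0:
        return positives.reset_index(drop=True)

    rng = np.random.default_rng(seed)
    case_order = rng.permutation(len(positives))
    ctrl_age = controls["age"].to_numpy(dtype=float)
    available = np.ones(len(controls), dtype=bool)

    chosen: list[np.ndarray] = []
    for ci in case_order:
        age = float(positives["age"].iloc[ci])
        dist = np.abs(ctrl_age - age)
        eligible = np.nonzero(available & (dist <= age_window))[0]
        if len(eligible) < ratio:
            raise ValueError(
                f"insufficient eligible controls for case at positives row {ci}: "
                f"needed {ratio}, found {len(eligible)} within ±{age_window} years"
            )
        take = eligible[np.argsort(dist[eligible], kind="stable")][:ratio]
        available[take] = False
        chosen.append(take)

    matched = controls.iloc[np.concatenate(chosen)]
    return pd.concat([positives, matched], ignore_index=True)


def _apportion(n: int, fractions: tuple[float, float, float]) -> list[int]:
    # largest-remainder apportionment; ties broken by split order
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n - sum(counts)
    order = sorted(range(3), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_extract(table: pd.DataFrame, plan: SplitPlan) -> pd.DataFrame:
    """Assign split tags, stratified by label, largest-remainder rounding.

    Deterministic given ``plan.seed``; per-class counts in each split are
    within one row of the exact fractions.
    """
    plan.validate()
    labels = table["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("split_extract requires both classes present")

    rng = np.random.default_rng(plan.seed)
    split = np.empty(len(table), dtype=object)
    names = ("train", "continuous_validation", "test")
    for cls in sorted(np.unique(labels)):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        counts = _apportion(len(idx), plan.fractions)
        start = 0
        for name, c in zip(names, counts):
            split[idx[start : start + c]] = name
            start += c
    out = table.copy()
    out["split"] = split
    return out


def harmonize_features(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Restrict all tables to their common feature set and merge them.

    Returns the row-concatenated table and a report mapping table index ->
    features dropped from that table. Raises if the tables share no features.
    """
    if not tables:
        raise ValueError("no tables to harmonize")
    per_table = [feature_columns(t) for t in tables]
    common = [f for f in per_table[0] if all(f in cols for cols in per_table[1:])]
    if not common:
        raise ValueError("no common features across tables")
    dropped = {i: [f for f in cols if f not in common] for i, cols in enumerate(per_table)}
    meta = [c for c in tables[0].columns if c not in per_table[0]]
    merged = pd.concat([t[common + [m for m in meta if m in t.columns]] for t in tables], ignore_index=True)
    return merged, dropped


def filter_missingness(
    table: pd.DataFrame,
    max_missing: float = 0.30,
    scope: str = "train",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features whose missing fraction strictly exceeds ``max_missing``.

    The fraction is measured on training rows when split tags exist
    (``scope="train"``), or on the whole extract (``scope="pooled"`` or when
    no rows are tagged ``train``). A feature missing exactly the threshold
    fraction is retained.
    """
    if scope not in ("train", "pooled"):
        raise ValueError("scope must be 'train' or 'pooled'")
    rows = table
    if scope == "train" and "split" in table.columns and (table["split"] == "train").any():
        rows = table[table["split"] == "train"]
    dropped = [f for f in feature_columns(table) if rows[f].isna().mean() > max_missing]
    return table.drop(columns=dropped), dropped


@dataclass
class PreprocessState:
    """Training-set statistics: per-feature mean, population SD and raw median."""

    features: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    medians: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {"features": self.features, "means": self.means, "sds": self.sds, "medians": self.medians},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        d = json.loads(text)
        return cls(d["features"], d["means"], d["sds"], d["medians"])


def fit_preprocess(train: pd.DataFrame) -> PreprocessState:
    """Fit standardisation and imputation statistics on training rows.

    Means/SDs/medians are computed on observed (non-missing) entries; the SD
    convention is the population SD (divide by n). Zero-variance features
    are rejected by name.
    """
    features = feature_columns(train)
    means, sds, medians = {}, {}, {}
    for f in features:
        vals = train[f].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"feature {f!r} has no observed training values")
        sd = float(np.std(vals))
        if sd <= 0:
            raise ValueError(f"feature {f!r} has zero variance on training rows")
        means[f] = float(np.mean(vals))
        sds[f] = sd
        medians[f] = float(np.median(vals))
    return PreprocessState(features, means, sds, medians)


def impute_median(table: pd.DataFrame, state: PreprocessState) -> pd.DataFrame:
    """Replace missing entries with the raw-scale training median (idempotent)."""
    out = table.copy()
    for f in state.features:
        vals = out[f].to_numpy(dtype=float)
        out[f] = np.where(np.isnan(vals), state.medians[f], vals)
    return out


def apply_preprocess(table: pd.DataFrame, state: PreprocessState) -> pd.DataFrame:
    """Impute missing entries with the raw training median, then standardise.

    Imputing on the raw scale first and standardising afterwards makes the
    two operations commute for observed values, and maps every imputed entry
    to (median - mean) / SD.
    """
    out = impute_median(table, state)
    for f in state.features:
        out[f] = (out[f].to_numpy(dtype=float) - state.means[f]) / state.sds[f]
    return out
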