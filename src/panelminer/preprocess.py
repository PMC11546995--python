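"""Preprocessing chain for targeted-metabolomics cohorts.

Order of operations (fixed): exclude males → drop sparse features → impute
(LOD for metabolites, observed mean for numeric demographics) → one-hot
encode race and smoking → add the Kynurenine-to-Tryptophan ratio →
standardize continuous columns.

On the reference design (138 metabolites, 6 of them above the 30 %
missingness filter, plus age/BMI/race/smoking) this yields 132 retained
metabolites + 1 ratio + 8 demographic columns = 141 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._cohort import Cohort, warn
from .feature_select import FeatureSet

__all__ = [
    "PreprocessConfig",
    "ScalerParams",
    "exclude_males",
    "drop_sparse_features",
    "impute",
    "encode_demographics",
    "add_ratio",
    "standardize",
    "apply_standardize",
    "run_preprocess",
    "train_validation_split",
]

RACE_CATEGORIES = ("white", "African American", "other")
SMOKING_CATEGORIES = ("current smoker", "past smoker", "smoking history")


@dataclass
class PreprocessConfig:
    missing_threshold: float = 0.30
    lod: float | dict[str, float] = 0.05
    ratio_numerator: str = "Kynurenine"
    ratio_denominator: str = "Tryptophan"
    ratio_name: str = "Kyn/Trp"
    race_categories: tuple[str, ...] = RACE_CATEGORIES
    smoking_categories: tuple[str, ...] = SMOKING_CATEGORIES
    race_column: str = "race"
    smoking_column: str = "smoking"
    sex_column: str = "sex"

    def __post_init__(self) -> None:
        if not 0.0 < self.missing_threshold < 1.0:
            raise ValueError("missing_threshold must be in (0, 1)")

    def lod_for(self, feature: str) -> float | None:
        if isinstance(self.lod, dict):
            value = self.lod.get(feature)
            return None if value is None else float(value)
        return float(self.lod)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        for key in ("race_categories", "smoking_categories"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class ScalerParams:
    """Column means and population SDs fitted by :func:`standardize`."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------- #
def exclude_males(cohort: Cohort, config: PreprocessConfig | None = None) -> Cohort:
    """Keep female rows only and drop the sex column; no-op without one."""
    config = config or PreprocessConfig()
    sex = config.sex_column
    if sex not in cohort.data.columns:
        return cohort
    keep = cohort.data[sex].astype(str).str.upper().isin({"F", "FEMALE"})
    data = cohort.data.loc[keep].drop(columns=[sex])
    return cohort.with_data(data)


def drop_sparse_features(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> tuple[Cohort, FeatureSet]:
    """Remove features whose missing fraction strictly exceeds the threshold."""
    config = config or PreprocessConfig()
    frac = cohort.data[cohort.features].isna().mean()
    dropped = [c for c in cohort.features if frac[c] > config.missing_threshold]
    if len(dropped) == len(cohort.features):
        raise ValueError("all features exceed the missingness threshold")
    data = cohort.data.drop(columns=dropped)
    return cohort.with_data(data), FeatureSet("dropped_sparse", dropped)


def impute(cohort: Cohort, config: PreprocessConfig | None = None) -> Cohort:
    """LOD for missing metabolite values; observed mean for numeric demographics.

    Observed entries are never altered.  A missing metabolite with no
    configured detection limit is an error naming the feature.
    """
    config = config or PreprocessConfig()
    data = cohort.data.copy()
    for col in cohort.metabolites:
        if not data[col].isna().any():
            continue
        lod = config.lod_for(col)
        if lod is None:
            raise ValueError(f"missing values in metabolite {col!r} but no LOD configured")
        data[col] = data[col].fillna(lod)
    for col in cohort.features:
        if col in cohort.metabolites or not data[col].isna().any():
            continue
        if pd.api.types.is_numeric_dtype(data[col]):
            data[col] = data[col].fillna(data[col].mean())
        else:
            mode = data[col].mode(dropna=True)
            fill = mode.iloc[0] if len(mode) else "unknown"
            warn(f"categorical column {col!r} imputed with mode {fill!r}")
            data[col] = data[col].fillna(fill)
    return cohort.with_data(data)


def encode_demographics(cohort: Cohort, config: PreprocessConfig | None = None) -> Cohort:
    """One-hot encode race and smoking onto fixed category columns.

    Race levels outside the configured categories map to ``other`` with a
    warning; the smoking indicators cover the three named categories only,
    so e.g. never-smokers get an all-zero row.
    """
    config = config or PreprocessConfig()
    data = cohort.data.copy()
    new_demo = [c for c in cohort.demographics if c not in (config.race_column, config.smoking_column)]

    if config.race_column in data.columns:
        race = data[config.race_column].astype(str)
        unknown = ~race.isin(config.race_categories)
        if unknown.any():
            warn(f"{int(unknown.sum())} unknown race level(s) mapped to 'other'")
            race = race.where(~unknown, "other")
        for cat in config.race_categories:
            col = f"race_{cat.replace(' ', '_')}"
            data[col] = (race == cat).astype(int)
            new_demo.append(col)
        data = data.drop(columns=[config.race_column])

    if config.smoking_column in data.columns:
        smoking = data[config.smoking_column].astype(str)
        for cat in config.smoking_categories:
            col = f"smoking_{cat.replace(' ', '_')}"
            data[col] = (smoking == cat).astype(int)
            new_demo.append(col)
        data = data.drop(columns=[config.smoking_column])

    return Cohort(
        data=data,
        metabolites=tuple(c for c in cohort.metabolites if c in data.columns),
        demographics=tuple(new_demo),
    )


def add_ratio(cohort: Cohort, config: PreprocessConfig | None = None) -> Cohort:
    """Append the numerator/denominator metabolite ratio as a new column."""
    config = config or PreprocessConfig()
    num, den, name = config.ratio_numerator, config.ratio_denominator, config.ratio_name
    for col in (num, den):
        if col not in cohort.data.columns:
            raise ValueError(f"ratio column {col!r} absent from cohort")
    denominator = cohort.data[den]
    bad = denominator <= 0
    if bad.any():
        raise ValueError(
            f"non-positive denominator for samples {cohort.data.index[bad].tolist()[:5]}"
        )
    data = cohort.data.copy()
    data[name] = cohort.data[num] / denominator
    return cohort.with_data(data)


def standardize(
    cohort: Cohort, columns: list[str] | None = None
) -> tuple[Cohort, ScalerParams]:
    """Z-score continuous columns (population SD); 0/1 indicators untouched.

    Returns the fitted means and SDs so held-out data can be transformed
    with training-set moments only (:func:`apply_standardize`).
    """
    if cohort.data[cohort.features].isna().any().any():
        raise ValueError("standardize requires a fully imputed table")
    columns = columns if columns is not None else cohort.continuous_features()
    params = ScalerParams()
    data = cohort.data.copy()
    for col in columns:
        x = data[col].to_numpy(dtype=float)
        mean, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0.0:
            warn(f"zero-variance column {col!r} left unscaled")
            continue
        params.means[col] = mean
        params.sds[col] = sd
        data[col] = (x - mean) / sd
    return cohort.with_data(data), params


def apply_standardize(cohort: Cohort, params: ScalerParams) -> Cohort:
    """Transform with previously fitted moments (no refitting)."""
    data = cohort.data.copy()
    for col, mean in params.means.items():
        if col in data.columns:
            data[col] = (data[col].to_numpy(dtype=float) - mean) / params.sds[col]
    return cohort.with_data(data)


def run_preprocess(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> tuple[Cohort, dict]:
    """Full chain; returns the clean cohort and a JSON-serialisable report."""
    config = config or PreprocessConfig()
    n0 = len(cohort.data)
    cohort = exclude_males(cohort, config)
    n_excluded = n0 - len(cohort.data)
    n_missing_before = int(cohort.data[cohort.features].isna().sum().sum())
    cohort, dropped = drop_sparse_features(cohort, config)
    cohort = impute(cohort, config)
    cohort = encode_demographics(cohort, config)
    has_ratio_cols = {config.ratio_numerator, config.ratio_denominator} <= set(cohort.data.columns)
    if has_ratio_cols:
        cohort = add_ratio(cohort, config)
    cohort, scaler = standardize(cohort)
    report = {
        "n_samples": len(cohort.data),
        "n_excluded_males": n_excluded,
        "dropped_sparse_features": list(dropped.members),
        "n_retained_metabolites": len(cohort.metabolites),
        "n_imputed_values": n_missing_before
        - int(cohort.data[cohort.features].isna().sum().sum()),
        "n_features": len(cohort.features),
        "ratio_added": has_ratio_cols,
        "standardized_columns": sorted(scaler.means),
    }
    return cohort, report


def train_validation_split(
    cohort: Cohort, validation_fraction: float = 0.20, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Optional stratified hold-out split; unused by the default pipeline."""
    rng = np.random.default_rng(seed)
    idx = cohort.data.index.to_numpy()
    labels = cohort.labels
    val_idx = []
    for cls in (0, 1):
        members = idx[labels == cls]
        k = int(round(validation_fraction * len(members)))
        val_idx.extend(rng.choice(members, size=k, replace=False))
    val_mask = cohort.data.index.isin(val_idx)
    return (
        cohort.with_data(cohort.data.loc[~val_mask]),
        cohort.with_data(cohort.data.loc[val_mask]),
    )
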