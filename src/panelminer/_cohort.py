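"""Shared cohort container and CSV round-trip.

A cohort is a samples × features table with a binary group label
(case = 1, control = 0).  Columns fall into three classes:

* **metabolites** — concentrations in µM, non-negative where observed,
  possibly missing (imputed later with the instrument detection limit);
* **demographics** — age, BMI, sex and the categorical race / smoking
  columns, plus their one-hot indicator columns after encoding;
* anything else (e.g. an engineered metabolite ratio) is a derived
  continuous feature.

The on-disk format is plain CSV: ``sample_id, group, <feature columns>``,
missing entries written as empty fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUP = "group"
SAMPLE_ID = "sample_id"

#: column names recognised as demographic when reading a bare CSV
KNOWN_DEMOGRAPHICS = frozenset({"age", "BMI", "sex", "race", "smoking"})
DEMOGRAPHIC_PREFIXES = ("race_", "smoking_")


@dataclass
class Cohort:
    """Samples × features table with a binary group label.

    Parameters
    ----------
    data : DataFrame indexed by sample id, containing a ``group`` column
        (0 = control, 1 = case) and one column per feature.
    metabolites : feature columns holding metabolite concentrations.
    demographics : feature columns holding demographic covariates.
    """

    data: pd.DataFrame
    metabolites: tuple[str, ...] = field(default_factory=tuple)
    demographics: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.metabolites = tuple(self.metabolites)
        self.demographics = tuple(self.demographics)
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        df = self.data
        if GROUP not in df.columns:
            raise ValueError(f"cohort is missing a '{GROUP}' column")
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature columns: {dupes[:5]}")
        groups = set(pd.unique(df[GROUP].dropna()))
        if not groups <= {0, 1}:
            raise ValueError(f"group labels must be binary 0/1, got {sorted(groups)}")
        missing_cols = [c for c in (*self.metabolites, *self.demographics) if c not in df.columns]
        if missing_cols:
            raise ValueError(f"declared features absent from table: {missing_cols[:5]}")

    def check_concentrations(self) -> None:
        """Raw-scale check: observed metabolite concentrations must be >= 0.

        Called on freshly generated or loaded tables; standardized tables
        are legitimately signed and skip this.
        """
        for col in self.metabolites:
            observed = self.data[col].dropna()
            if len(observed) and (pd.to_numeric(observed) < 0).any():
                raise ValueError(f"negative concentration in metabolite column {col!r}")

    # ------------------------------------------------------------------ #
    @property
    def features(self) -> list[str]:
        return [c for c in self.data.columns if c != GROUP]

    @property
    def n_cases(self) -> int:
        return int((self.data[GROUP] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data[GROUP] == 0).sum())

    @property
    def labels(self) -> np.ndarray:
        return self.data[GROUP].to_numpy(dtype=int)

    def numeric_features(self) -> list[str]:
        return [c for c in self.features if pd.api.types.is_numeric_dtype(self.data[c])]

    def continuous_features(self) -> list[str]:
        """Numeric feature columns that are not 0/1 indicators."""
        out = []
        for c in self.numeric_features():
            observed = self.data[c].dropna().unique()
            if not set(np.asarray(observed, dtype=float)) <= {0.0, 1.0}:
                out.append(c)
        return out

    def with_data(self, data: pd.DataFrame) -> "Cohort":
        """New cohort around ``data``, keeping only still-present feature roles."""
        return Cohort(
            data=data,
            metabolites=tuple(c for c in self.metabolites if c in data.columns),
            demographics=tuple(c for c in self.demographics if c in data.columns),
        )

    def copy(self) -> "Cohort":
        return replace(self, data=self.data.copy())

    def equals(self, other: "Cohort") -> bool:
        return (
            self.data.equals(other.data)
            and self.metabolites == other.metabolites
            and self.demographics == other.demographics
        )


# ---------------------------------------------------------------------- #
# CSV round-trip
# ---------------------------------------------------------------------- #
def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write ``sample_id, group, features...`` CSV; missing values as empty fields."""
    out = cohort.data.reset_index(names=SAMPLE_ID)
    out.to_csv(path, index=False)


def read_cohort_csv(
    path,
    metabolites: tuple[str, ...] | None = None,
    demographics: tuple[str, ...] | None = None,
) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    When the column roles are not given they are inferred: known demographic
    names (and ``race_*`` / ``smoking_*`` indicators) are demographic, columns
    containing ``/`` are derived ratios, everything else is a metabolite.
    """
    df = pd.read_csv(path, index_col=SAMPLE_ID)
    feature_cols = [c for c in df.columns if c != GROUP]
    if demographics is None:
        demographics = tuple(
            c
            for c in feature_cols
            if c in KNOWN_DEMOGRAPHICS or c.startswith(DEMOGRAPHIC_PREFIXES)
        )
    if metabolites is None:
        metabolites = tuple(
            c for c in feature_cols if c not in set(demographics) and "/" not in c
        )
    return Cohort(data=df, metabolites=metabolites, demographics=demographics)


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=3)
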