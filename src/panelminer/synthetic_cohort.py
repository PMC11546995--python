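"""Synthetic plasma-metabolomics cohort generator.

Emulates the statistical structure of a targeted-metabolomics case/control
study of breast cancer: a heavily imbalanced cohort (185 cases vs 53
controls by default), 138 measured metabolites of which a handful exceed a
30 % missingness filter, demographic covariates (age, BMI, race, smoking),
an age confound (cases are older), and a configurable subset of genuinely
discriminative metabolites.

Model
-----
Metabolite concentrations are log-normal: for feature *j*,
``log x_ij ~ Normal(mu_j, sigma_j)``, with a per-feature baseline ``mu_j``
drawn once per cohort.  A planted case effect of ``d`` pooled-SD units is an
additive shift of ``d * sigma_j`` on the log scale, so concentrations remain
positive and the standardised group separation on the log scale is ``d``.
Missingness is missing-completely-at-random with an *exact* per-feature
count ``round(rate * n)``, so the empirical missing fraction always matches
the configured rate to within 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._cohort import GROUP, Cohort, read_cohort_csv, write_cohort_csv

__all__ = ["SimConfig", "generate_cohort", "write_fixture", "read_fixture"]

RACE_LEVELS = ("white", "African American", "other")
SMOKING_LEVELS = ("never", "current smoker", "past smoker", "smoking history")

#: metabolites named in targeted plasma panels; the remainder of the 138-analyte
#: catalogue is filled with generic ``Met###`` identifiers.
NAMED_METABOLITES = (
    "Kynurenine",
    "Tryptophan",
    "Glutamine",
    "Methionine",
    "Valine",
    "Asparagine",
    "Creatinine",
    "Citric acid",
    "C0",
    "C3OH",
    "C14:2OH",
    "C16:2OH",
    "SM C18:0",
    "SM(OH) C22:2",
    "SM(OH) C16:1",
    "LysoPC a C16:0",
    "LysoPC a C18:1",
    "PC aa C36:0",
)

#: default planted case effects (pooled-SD units on the log scale): the nine
#: panel metabolites plus the kynurenine-pathway pair that makes the
#: Kynurenine-to-Tryptophan ratio informative.
DEFAULT_PLANTED: tuple[tuple[str, float], ...] = (
    ("SM(OH) C22:2", 1.5),
    ("SM C18:0", 1.5),
    ("C0", 1.5),
    ("C3OH", 1.5),
    ("C14:2OH", 1.5),
    ("C16:2OH", 1.5),
    ("LysoPC a C18:1", -1.5),
    ("PC aa C36:0", -1.5),
    ("Asparagine", 1.5),
    ("Kynurenine", 0.8),
    ("Tryptophan", -0.8),
)


def default_feature_names(n_metabolites: int) -> tuple[str, ...]:
    names = list(NAMED_METABOLITES[:n_metabolites])
    i = len(names)
    while len(names) < n_metabolites:
        i += 1
        candidate = f"Met{i:03d}"
        if candidate not in names:
            names.append(candidate)
    return tuple(names)


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults reproduce the reference design: 185 cases, 53 controls,
    138 metabolites with 6 sparse (40 % missing) columns, a planted
    +8-year age shift in cases, and eleven discriminative metabolites.
    """

    n_cases: int = 185
    n_controls: int = 53
    n_metabolites: int = 138
    feature_names: tuple[str, ...] | None = None
    planted_features: tuple[tuple[str, float], ...] = DEFAULT_PLANTED
    sparse_features: tuple[str, ...] = ("Met019", "Met020", "Met021", "Met022", "Met023", "Met024")
    missing_rate: float = 0.02
    sparse_missing_rate: float = 0.40
    lod: float | dict[str, float] = 0.05          # µM
    log_sigma: float = 0.5                        # dispersion of log-concentrations
    age_effect: float = 8.0                       # years, case minus control mean
    age_mean: float = 50.0
    age_sd: float = 10.0
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    race_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    smoking_probs: tuple[float, ...] = (0.5, 0.2, 0.2, 0.1)
    male_fraction: float = 0.0                    # > 0 adds a 'sex' column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_names is None:
            self.feature_names = default_feature_names(self.n_metabolites)
        self.feature_names = tuple(self.feature_names)
        self.planted_features = tuple((str(f), float(e)) for f, e in self.planted_features)
        # planted features outside the catalogue are dropped rather than
        # rejected so that a smaller n_metabolites keeps working defaults
        self.planted_features = tuple(
            (f, e) for f, e in self.planted_features if f in self.feature_names
        )
        self.sparse_features = tuple(f for f in self.sparse_features if f in self.feature_names)
        self.validate()

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if len(self.feature_names) != self.n_metabolites:
            raise ValueError(
                f"{len(self.feature_names)} feature names for n_metabolites={self.n_metabolites}"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        for rate in (self.missing_rate, self.sparse_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate {rate} outside [0, 1]")
        for name, lod in self.lod_map().items():
            if lod <= 0:
                raise ValueError(f"LOD for {name!r} must be > 0")
        planted = {f for f, _ in self.planted_features}
        if self.sparse_missing_rate >= 1.0 and planted & set(self.sparse_features):
            raise ValueError("planted feature would be missing at rate 1")
        if self.missing_rate >= 1.0 and planted:
            raise ValueError("planted feature would be missing at rate 1")
        if abs(sum(self.race_probs) - 1) > 1e-9 or abs(sum(self.smoking_probs) - 1) > 1e-9:
            raise ValueError("category probabilities must sum to 1")

    def lod_map(self) -> dict[str, float]:
        if isinstance(self.lod, dict):
            return {name: float(self.lod.get(name, 0.05)) for name in self.feature_names}
        return {name: float(self.lod) for name in self.feature_names}

    # -- YAML round-trip ------------------------------------------------ #
    def to_yaml(self, path) -> None:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()
        }
        payload["planted_features"] = [[f, e] for f, e in self.planted_features]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if payload.get("planted_features"):
            payload["planted_features"] = [tuple(p) for p in payload["planted_features"]]
        return cls(**payload)


def _exact_missing_mask(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Boolean mask with exactly round(rate * n) True entries."""
    k = int(round(rate * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=min(k, n), replace=False)] = True
    return mask


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort from the generative model described in the module docstring.

    Deterministic under a fixed ``config.seed``: the same config yields a
    byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    group = np.concatenate([np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    effects = dict(config.planted_features)
    sigma = config.log_sigma
    columns: dict[str, np.ndarray | list] = {GROUP: group}

    # per-feature baseline medians, log-normal across the catalogue
    mu = rng.normal(np.log(10.0), 1.0, size=config.n_metabolites)
    for j, name in enumerate(config.feature_names):
        log_x = rng.normal(mu[j], sigma, size=n)
        if name in effects:
            log_x[group == 1] += effects[name] * sigma
        values = np.exp(log_x)
        rate = config.sparse_missing_rate if name in config.sparse_features else config.missing_rate
        mask = _exact_missing_mask(rng, n, rate)
        values = values.astype(float)
        values[mask] = np.nan
        columns[name] = values

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age[group == 1] += config.age_effect
    columns["age"] = np.round(age, 1)
    columns["BMI"] = np.round(np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 15, None), 1)
    columns["race"] = rng.choice(RACE_LEVELS, size=n, p=config.race_probs).tolist()
    columns["smoking"] = rng.choice(SMOKING_LEVELS, size=n, p=config.smoking_probs).tolist()

    demographics = ["age", "BMI", "race", "smoking"]
    if config.male_fraction > 0:
        sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
        columns["sex"] = sex.tolist()
        demographics.append("sex")

    data = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    cohort = Cohort(data=data, metabolites=config.feature_names, demographics=tuple(demographics))
    cohort.check_concentrations()
    return cohort


def write_fixture(cohort: Cohort, path) -> None:
    """Serialize a cohort to CSV (missing entries become empty fields)."""
    write_cohort_csv(cohort, path)


def read_fixture(path, **kwargs) -> Cohort:
    return read_cohort_csv(path, **kwargs)
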