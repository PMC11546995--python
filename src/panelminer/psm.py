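"""Propensity-score matching for imbalanced case/control cohorts.

The propensity score — the probability of belonging to the case group given
the covariates — is estimated with a 100-tree random forest.  Each case is
then matched to its nearest three controls by absolute propensity
difference (with replacement), and controls that several distinct cases
select are duplicated into the cohort, growing the control arm toward the
case arm.  Standardized mean differences before/after matching serve as the
balance diagnostic.

Because matching is with replacement from a small control pool, the
augmentation rule matters: by default each control contributes at most one
duplicate row, however many cases select it, and the control arm never
grows beyond the case arm.  Both limits are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._cohort import GROUP, Cohort, warn

__all__ = ["MatchConfig", "MatchResult", "fit_propensity", "match_controls", "balance_check"]


@dataclass
class MatchConfig:
    n_trees: int = 100
    n_neighbors: int = 3
    with_replacement: bool = True
    caliper: float | None = None              # max |propensity difference|; off by default
    max_extra_per_control: int | None = None  # per-control duplicate limit (None = unbounded)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_neighbors < 1:
            raise ValueError("n_trees and n_neighbors must be >= 1")


@dataclass
class MatchResult:
    propensity: pd.Series
    pairs: list[tuple[str, str, float]]     # (treated id, control id, |Δ score|)
    augmented: Cohort
    n_additional_controls: int

    def report(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "n_additional_controls": self.n_additional_controls,
            "pairs": [[t, c, float(d)] for t, c, d in self.pairs],
            "propensity": {k: float(v) for k, v in self.propensity.items()},
            "note": (
                "augmentation duplicates re-selected controls (at most "
                "max_extra_per_control copies each, control arm capped at the "
                "case-arm size); this rule is an interpretation of matching "
                "with replacement from a small control pool"
            ),
        }


def fit_propensity(
    cohort: Cohort,
    config: MatchConfig | None = None,
    covariates: list[str] | None = None,
) -> pd.Series:
    """Per-sample case-membership probability from a random forest.

    Uses out-of-bag probabilities where available (they behave better than
    the full-fit probabilities on separable data, which saturate at 0/1);
    samples never out of bag fall back to the full-fit probability.

    The default covariates are the cohort's numeric demographic columns —
    the confounders that matching is meant to balance; falling back to all
    numeric features when no demographics are declared.  Pass ``covariates``
    explicitly to override.
    """
    if covariates is None:
        covariates = [
            c for c in cohort.demographics
            if c in cohort.data.columns and pd.api.types.is_numeric_dtype(cohort.data[c])
        ] or cohort.numeric_features()
    X = cohort.data[covariates].to_numpy(dtype=float)
    y = cohort.labels
    if len(set(y)) < 2:
        raise ValueError("propensity model needs both classes")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees if config else 100,
        oob_score=True,
        bootstrap=True,
        random_state=(config.seed if config else 0),
    )
    forest.fit(X, y)
    case_col = list(forest.classes_).index(1)
    scores = forest.oob_decision_function_[:, case_col]
    fallback = forest.predict_proba(X)[:, case_col]
    scores = np.where(np.isnan(scores), fallback, scores)
    return pd.Series(scores, index=cohort.data.index, name="propensity")


def match_controls(
    scores: pd.Series, cohort: Cohort, config: MatchConfig | None = None
) -> MatchResult:
    """Nearest-neighbor matching on propensity scores, plus control augmentation.

    For each case the ``n_neighbors`` controls with smallest absolute
    propensity difference are recorded (ties broken by control position in
    the table).  Controls selected by more than one distinct case are then
    appended as duplicate rows, up to ``max_extra_per_control`` copies each
    and never growing the control arm past the case arm; the most
    frequently selected controls are duplicated first.
    """
    config = config or MatchConfig()
    labels = cohort.data[GROUP]
    treated_ids = list(cohort.data.index[labels == 1])
    control_ids = list(cohort.data.index[labels == 0])
    if len(control_ids) < config.n_neighbors:
        raise ValueError(
            f"{len(control_ids)} controls but n_neighbors={config.n_neighbors}"
        )
    missing = [s for s in cohort.data.index if s not in scores.index]
    if missing:
        raise ValueError(f"scores missing for samples {missing[:5]}")

    ctrl_scores = scores.loc[control_ids].to_numpy(dtype=float)
    pairs: list[tuple[str, str, float]] = []
    selections: dict[str, set[str]] = {c: set() for c in control_ids}
    for t in treated_ids:
        dist = np.abs(ctrl_scores - float(scores.loc[t]))
        order = np.lexsort((np.arange(len(control_ids)), dist))  # tie → index order
        picked = 0
        for j in order:
            if picked >= config.n_neighbors:
                break
            if config.caliper is not None and dist[j] > config.caliper:
                continue
            cid = control_ids[j]
            pairs.append((t, cid, float(dist[j])))
            selections[cid].add(t)
            picked += 1

    # augmentation: one duplicate per extra distinct case selecting a control,
    # optionally limited per control, allocated round-robin (most-selected
    # controls first) under a global cap of total controls <= total cases
    counts = {c: len(s) for c, s in selections.items()}
    cap = max(0, len(treated_ids) - len(control_ids))
    budget = {}
    for c in control_ids:
        extras = max(counts[c] - 1, 0)
        if config.max_extra_per_control is not None:
            extras = min(extras, config.max_extra_per_control)
        budget[c] = extras
    dup_order = sorted(control_ids, key=lambda c: (-counts[c], control_ids.index(c)))
    extra_rows = []
    copies = {c: 0 for c in control_ids}
    while len(extra_rows) < cap and any(budget[c] > copies[c] for c in control_ids):
        for c in dup_order:
            if len(extra_rows) >= cap:
                break
            if budget[c] > copies[c]:
                copies[c] += 1
                row = cohort.data.loc[[c]].copy()
                row.index = [f"{c}_dup{copies[c]}"]
                extra_rows.append(row)

    augmented_df = pd.concat([cohort.data, *extra_rows]) if extra_rows else cohort.data.copy()
    augmented = cohort.with_data(augmented_df)
    return MatchResult(
        propensity=scores,
        pairs=pairs,
        augmented=augmented,
        n_additional_controls=len(extra_rows),
    )


def _smd(data: pd.DataFrame, covariates: list[str]) -> pd.Series:
    cases = data[data[GROUP] == 1]
    controls = data[data[GROUP] == 0]
    out = {}
    for cov in covariates:
        a = cases[cov].to_numpy(dtype=float)
        b = controls[cov].to_numpy(dtype=float)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        if pooled == 0 or np.isnan(pooled):
            warn(f"zero pooled SD for covariate {cov!r}; SMD reported as 0")
            out[cov] = 0.0
        else:
            out[cov] = float(abs(a.mean() - b.mean()) / pooled)
    return pd.Series(out, name="smd")


def balance_check(
    before: Cohort, after: Cohort, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Standardized mean difference per covariate, before vs after matching."""
    if covariates is None:
        covariates = [c for c in before.numeric_features() if c in after.data.columns]
    else:
        absent = [c for c in covariates if c not in before.data.columns or c not in after.data.columns]
        if absent:
            raise ValueError(f"covariates absent from a table: {absent[:5]}")
    return pd.DataFrame(
        {"smd_before": _smd(before.data, covariates), "smd_after": _smd(after.data, covariates)}
    )
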