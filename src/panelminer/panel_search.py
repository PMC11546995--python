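"""Random panel sampling over the selector union, consolidation, pruning.

The search draws thousands of random candidate panels (size uniform on a
small range, members uniform without replacement) from the pooled selector
features, scores each by cross-validated mean AUC, retains the high
performers (above an absolute AUC threshold, or the top fraction when a
retention quantile is configured), and consolidates them: features that
recur in at least ``core_frequency`` high-performing panels form the core
panel.  A final greedy backward pass scores every leave-one-feature-out
subset of the core panel (by leave-one-sample-out AUC by default) and
recurses once, producing the (k−1)- and (k−2)-feature refinements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut

from ._cohort import Cohort, warn
from .evaluate import EvalConfig, _standardize_fold, cv_mean_auc, replace_params
from .feature_select import FeatureSet

__all__ = [
    "PanelSearchConfig",
    "PanelSearchResult",
    "sample_panels",
    "consolidate",
    "prune_by_feature_loocv",
]


@dataclass
class PanelSearchConfig:
    n_iterations: int = 15000
    panel_size_min: int = 9
    panel_size_max: int = 12
    auc_threshold: float = 0.95
    retain_fraction: float | None = None   # overrides auc_threshold with a top-quantile rule
    core_frequency: int = 4
    #: when set, the consolidation threshold becomes
    #: max(core_frequency, ceil(core_fraction * n_high_performers)) — scale-aware
    #: consolidation for searches retaining many panels, since the chance
    #: frequency of any feature grows linearly with the retained count
    core_fraction: float | None = None
    seed: int = 0
    #: scorer for the search loop; the full-fidelity 10×50 harness is used
    #: only for final panels
    eval_config: EvalConfig = field(
        default_factory=lambda: EvalConfig(n_folds=10, n_repeats=5)
    )
    prune_scorer: str = "loocv"            # "loocv" or "cv"

    def __post_init__(self) -> None:
        if self.panel_size_min > self.panel_size_max:
            raise ValueError("panel_size_min must be <= panel_size_max")
        if not 0.0 < self.auc_threshold < 1.0:
            raise ValueError("auc_threshold must be in (0, 1)")
        if self.core_frequency < 1:
            raise ValueError("core_frequency must be >= 1")


@dataclass
class PanelSearchResult:
    panels: list[tuple[FeatureSet, float]]
    auc_threshold: float
    high_performers: list[tuple[FeatureSet, float]] = field(init=False)
    unique_biomarkers: FeatureSet = field(init=False)
    frequency_table: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.high_performers = [(p, a) for p, a in self.panels if a > self.auc_threshold]
        counts: dict[str, int] = {}
        seen: list[str] = []
        for panel, _ in self.high_performers:
            for f in panel:
                if f not in counts:
                    counts[f] = 0
                    seen.append(f)
                counts[f] += 1
        self.frequency_table = counts
        self.unique_biomarkers = FeatureSet("unique_biomarkers", seen)

    def to_json(self, path) -> None:
        payload = {
            "auc_threshold": self.auc_threshold,
            "n_panels": len(self.panels),
            "n_high_performers": len(self.high_performers),
            "frequency_table": self.frequency_table,
            "unique_biomarkers": list(self.unique_biomarkers),
            "panels": [
                {"members": list(p.members), "mean_auc": a} for p, a in self.panels
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, ensure_ascii=False)


def draw_panels(
    pool: FeatureSet, config: PanelSearchConfig, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """The random candidate panels, without scoring (seeded, reproducible)."""
    members = list(pool.members)
    sizes = rng.integers(config.panel_size_min, config.panel_size_max + 1,
                         size=config.n_iterations)
    return [
        tuple(str(f) for f in rng.choice(members, size=int(k), replace=False))
        for k in sizes
    ]


def sample_panels(
    pool: FeatureSet, cohort: Cohort, config: PanelSearchConfig | None = None
) -> PanelSearchResult:
    """Score ``n_iterations`` random panels from the pool by CV mean AUC."""
    config = config or PanelSearchConfig()
    if len(pool) == 0:
        raise ValueError("empty feature pool")
    if len(pool) < config.panel_size_max:
        raise ValueError(
            f"pool of {len(pool)} smaller than panel_size_max={config.panel_size_max}"
        )
    rng = np.random.default_rng(config.seed)
    candidates = draw_panels(pool, config, rng)

    feats = list(pool.members)
    col = {f: i for i, f in enumerate(feats)}
    X_all = cohort.data[feats].to_numpy(dtype=float)
    y = cohort.labels
    continuous = set(cohort.continuous_features())

    scored: list[tuple[FeatureSet, float]] = []
    for i, panel in enumerate(candidates):
        idx = [col[f] for f in panel]
        cont_mask = np.array([f in continuous for f in panel])
        auc = cv_mean_auc(X_all[:, idx], y, cont_mask, config.eval_config)
        scored.append((FeatureSet(f"panel_{i:05d}", panel), auc))

    threshold = config.auc_threshold
    if config.retain_fraction is not None:
        aucs = np.array([a for _, a in scored])
        threshold = float(np.quantile(aucs, 1.0 - config.retain_fraction))
    return PanelSearchResult(panels=scored, auc_threshold=threshold)


def consolidate(result: PanelSearchResult, config: PanelSearchConfig | None = None) -> FeatureSet:
    """Core panel: features appearing in >= core_frequency high-performing panels."""
    config = config or PanelSearchConfig()
    if not result.high_performers:
        warn("no high-performing panels; core panel is empty")
        return FeatureSet("core", [])
    threshold = config.core_frequency
    if config.core_fraction is not None:
        threshold = max(
            threshold, int(np.ceil(config.core_fraction * len(result.high_performers)))
        )
    freq = result.frequency_table
    members = sorted(
        [f for f, n in freq.items() if n >= threshold],
        key=lambda f: (-freq[f], f),
    )
    return FeatureSet("core", members)


# ---------------------------------------------------------------------- #
def _loocv_auc(X, y, cont_mask, eval_config: EvalConfig) -> float:
    """Leave-one-sample-out decision scores pooled into a single AUC."""
    clf_template = eval_config.classifier()
    scores = np.empty(len(y))
    for tr, te in LeaveOneOut().split(X):
        X_tr, X_te = _standardize_fold(X[tr], X[te], cont_mask)
        clf = replace_params(clf_template)
        clf.fit(X_tr, y[tr])
        scores[te[0]] = clf.decision_function(X_te)[0]
    return float(roc_auc_score(y, scores))


@dataclass
class PruneStep:
    candidates: dict[str, float]    # removed feature -> score of the remaining subset
    removed: str
    panel: FeatureSet
    score: float


@dataclass
class PruneResult:
    subsets: list[tuple[FeatureSet, float]]
    trace: list[PruneStep]


def prune_by_feature_loocv(
    panel: FeatureSet,
    cohort: Cohort,
    config: PanelSearchConfig | None = None,
    n_rounds: int = 2,
) -> PruneResult:
    """Greedy backward refinement of a panel, two rounds by default.

    Each round scores every leave-one-feature-out subset (leave-one-sample-
    out AUC by default, or the repeated-CV scorer when
    ``config.prune_scorer == "cv"``) and drops the feature whose removal
    scores best; ties break by removing the lexicographically smallest
    feature name.  The full candidate score trace is returned so the
    refinement can be audited.
    """
    config = config or PanelSearchConfig()
    if len(panel) < 2:
        raise ValueError("panel must have at least 2 features to prune")
    y = cohort.labels
    continuous = set(cohort.continuous_features())

    def score_subset(members: tuple[str, ...]) -> float:
        X = cohort.data[list(members)].to_numpy(dtype=float)
        cont_mask = np.array([f in continuous for f in members])
        if config.prune_scorer == "loocv":
            return _loocv_auc(X, y, cont_mask, config.eval_config)
        return cv_mean_auc(X, y, cont_mask, config.eval_config)

    current = panel
    trace: list[PruneStep] = []
    subsets: list[tuple[FeatureSet, float]] = []
    for _ in range(min(n_rounds, len(panel) - 1)):
        candidates = {}
        for removed in current.members:
            remaining = tuple(f for f in current.members if f != removed)
            candidates[removed] = score_subset(remaining)
        removed = min(candidates, key=lambda f: (-candidates[f], f))
        remaining = tuple(f for f in current.members if f != removed)
        current = FeatureSet(f"{panel.name}-{len(remaining)}", remaining)
        step = PruneStep(
            candidates=candidates, removed=removed, panel=current, score=candidates[removed]
        )
        trace.append(step)
        subsets.append((current, candidates[removed]))
    return PruneResult(subsets=subsets, trace=trace)
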