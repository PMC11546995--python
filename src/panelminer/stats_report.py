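"""Per-feature differential statistics and plot-ready exports.

Backs the three standard views of a selected biomarker panel: per-feature
Wilcoxon rank-sum tests (violin-plot annotations), a per-feature z-score
matrix with a group key (heatmap), and a two-component PCA projection of
the samples (scatter).  Rendering is left to the caller; only the
underlying numbers are produced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._cohort import GROUP, Cohort, warn
from .feature_select import FeatureSet

__all__ = ["FeatureTestResult", "wilcoxon_table", "zscore_matrix", "pca_projection"]


@dataclass
class FeatureTestResult:
    feature: str
    statistic: float
    p_value: float
    median_case: float
    median_control: float


def _members(features) -> list[str]:
    return list(features.members) if isinstance(features, FeatureSet) else list(features)


def wilcoxon_table(
    cohort: Cohort,
    features,
    correction: str | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per feature.

    The exact null distribution is enumerated when both groups have at most
    10 samples and the feature has no ties; otherwise the normal
    approximation with tie correction (and continuity correction) is used.
    Raw p-values by default; ``correction="bh"`` appends Benjamini–Hochberg
    adjusted values.
    """
    labels = cohort.labels
    cases = cohort.data.loc[labels == 1]
    controls = cohort.data.loc[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for feat in _members(features):
        a = cases[feat].to_numpy(dtype=float)
        b = controls[feat].to_numpy(dtype=float)
        small = len(a) <= 10 and len(b) <= 10
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            FeatureTestResult(
                feature=feat,
                statistic=float(res.statistic),
                p_value=float(min(res.pvalue, 1.0)),
                median_case=float(np.median(a)),
                median_control=float(np.median(b)),
            ).__dict__
        )
    table = pd.DataFrame(rows)
    if correction == "bh":
        table["p_adjusted"] = _benjamini_hochberg(table["p_value"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def zscore_matrix(cohort: Cohort, features) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature z-scores across all samples, plus the group key.

    Zero-variance features become all-zero rows with a warning.  Rows are
    features, columns are samples (heatmap orientation).
    """
    feats = _members(features)
    block = cohort.data[feats]
    if block.isna().any().any():
        raise ValueError("zscore_matrix requires a fully imputed table")
    X = block.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warn(f"zero-variance feature(s) {list(np.array(feats)[zero])[:5]} set to 0")
    Z = np.where(zero, 0.0, (X - mean) / np.where(zero, 1.0, sd))
    matrix = pd.DataFrame(Z.T, index=feats, columns=cohort.data.index)
    groups = cohort.data[GROUP].copy()
    return matrix, groups


def pca_projection(cohort: Cohort, features, n_components: int = 2) -> pd.DataFrame:
    """First principal-component scores per sample, sign-fixed.

    Each component's sign is chosen so its largest-|loading| feature loads
    positively, making projections comparable across runs.  Rank-deficient
    input degrades to fewer components with a warning.
    """
    feats = _members(features)
    if len(feats) < 2:
        raise ValueError("PCA projection needs at least 2 features")
    X = cohort.data[feats].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank, X.shape[0] - 1, len(feats))
    if k < n_components:
        warn(f"input supports only {k} component(s)")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    for c in range(k):
        lead = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, lead] < 0:
            scores[:, c] *= -1
    out = pd.DataFrame(
        scores, index=cohort.data.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    out[GROUP] = cohort.data[GROUP]
    return out
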