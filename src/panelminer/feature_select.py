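"""The three base feature selectors feeding the set-algebra catalogue.

* :func:`nb_univariate_select` — per-feature Gaussian naive-Bayes screen:
  each feature is evaluated alone over many stratified random splits and
  ranked by mean accuracy (ties: mean F1, then name); top-k returned.
* :func:`svc_l2_select` — linear SVC with an L2 penalty (C = 0.001, dual
  formulation) fitted once; features whose |coefficient| is at least the
  mean |coefficient| are kept (the conventional select-from-model rule,
  since an L2 penalty produces no exact zeros).
* :func:`pca_loading_select` — PCA with a fixed number of components;
  features ranked by squared loadings weighted by each component's
  eigenvalue excess over the Marchenko–Pastur noise bulk, so components
  indistinguishable from sampling noise contribute nothing, and the top
  ``pca_n_features`` kept.  A per-component round-robin allocation is
  available as an alternative (``pca_allocation="round_robin"``), but it
  spreads the budget uniformly over components and so dilutes a signal
  concentrated on one axis across noise components.

Each selector views feature importance differently (predictive accuracy,
margin coefficients, variance structure), which is the point of combining
them downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import LinearSVC

__all__ = [
    "FeatureSet",
    "SelectorConfig",
    "nb_univariate_select",
    "svc_l2_select",
    "pca_loading_select",
]


@dataclass(frozen=True)
class FeatureSet:
    """A named, ordered, duplicate-free collection of feature identifiers."""

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members) -> None:
        members = tuple(members)
        if len(set(members)) != len(members):
            raise ValueError(f"duplicate members in feature set {name!r}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members

    def as_set(self) -> frozenset:
        return frozenset(self.members)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "members": list(self.members)}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FeatureSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["name"], payload["members"])


@dataclass
class SelectorConfig:
    nb_top_k: int = 15
    nb_n_splits: int = 100
    nb_test_fraction: float = 0.20
    svc_C: float = 0.001
    svc_dual: bool = True
    pca_components: int = 8
    pca_n_features: int = 50
    pca_allocation: str = "weighted"   # or "round_robin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_top_k < 1 or self.pca_components < 1:
            raise ValueError("nb_top_k and pca_components must be >= 1")
        if self.svc_C <= 0:
            raise ValueError("svc_C must be > 0")
        if self.pca_n_features < self.pca_components:
            raise ValueError("pca_n_features must be >= pca_components")


def _design(cohort, features):
    feats = list(features) if features is not None else cohort.numeric_features()
    X = cohort.data[feats].to_numpy(dtype=float)
    y = cohort.labels
    return feats, X, y


# ---------------------------------------------------------------------- #
# Univariate naive Bayes
# ---------------------------------------------------------------------- #
def _nb_scores_one_split(X_tr, y_tr, X_te, y_te):
    """Vectorised per-feature Gaussian NB accuracy and F1 for one split.

    Equivalent to fitting ``sklearn.naive_bayes.GaussianNB`` on each single
    feature column (same variance smoothing rule), but evaluates all
    features at once.
    """
    eps = 1e-9 * X_tr.var(axis=0)  # sklearn's var_smoothing on a 1-feature fit
    out_acc = np.empty(X_tr.shape[1])
    out_f1 = np.empty(X_tr.shape[1])
    log_like = np.empty((2, X_te.shape[0], X_te.shape[1]))
    for cls in (0, 1):
        Xc = X_tr[y_tr == cls]
        mean = Xc.mean(axis=0)
        var = Xc.var(axis=0) + eps
        prior = np.log(Xc.shape[0] / X_tr.shape[0])
        log_like[cls] = (
            -0.5 * np.log(2 * np.pi * var)
            - (X_te - mean) ** 2 / (2 * var)
            + prior
        )
    pred = (log_like[1] > log_like[0]).astype(int)  # n_test × p
    truth = y_te[:, None]
    out_acc[:] = (pred == truth).mean(axis=0)
    tp = ((pred == 1) & (truth == 1)).sum(axis=0)
    fp = ((pred == 1) & (truth == 0)).sum(axis=0)
    fn = ((pred == 0) & (truth == 1)).sum(axis=0)
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        out_f1[:] = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    return out_acc, out_f1


def nb_univariate_select(
    cohort, config: SelectorConfig | None = None, features: list[str] | None = None
) -> FeatureSet:
    """Rank features by single-feature Gaussian NB accuracy over random splits."""
    config = config or SelectorConfig()
    feats, X, y = _design(cohort, features)
    if config.nb_top_k > len(feats):
        raise ValueError(f"nb_top_k={config.nb_top_k} exceeds {len(feats)} features")
    splitter = StratifiedShuffleSplit(
        n_splits=config.nb_n_splits,
        test_size=config.nb_test_fraction,
        random_state=config.seed,
    )
    acc = np.zeros(len(feats))
    f1 = np.zeros(len(feats))
    for tr, te in splitter.split(X, y):
        a, f = _nb_scores_one_split(X[tr], y[tr], X[te], y[te])
        acc += a
        f1 += f
    acc /= config.nb_n_splits
    f1 /= config.nb_n_splits
    order = sorted(range(len(feats)), key=lambda j: (-acc[j], -f1[j], feats[j]))
    top = [feats[j] for j in order[: config.nb_top_k]]
    return FeatureSet("NB", top)


# ---------------------------------------------------------------------- #
# L2 linear SVC
# ---------------------------------------------------------------------- #
def svc_l2_select(
    cohort, config: SelectorConfig | None = None, features: list[str] | None = None
) -> FeatureSet:
    """Select features with |coefficient| >= mean |coefficient| of a linear SVC."""
    config = config or SelectorConfig()
    feats, X, y = _design(cohort, features)
    model = LinearSVC(
        penalty="l2",
        C=config.svc_C,
        dual=config.svc_dual,
        random_state=config.seed,
        max_iter=20000,
    )
    model.fit(X, y)
    coefs = np.abs(model.coef_.ravel())
    threshold = coefs.mean()
    chosen = [j for j in range(len(feats)) if coefs[j] >= threshold]
    chosen.sort(key=lambda j: (-coefs[j], feats[j]))
    return FeatureSet("SVC", [feats[j] for j in chosen])


# ---------------------------------------------------------------------- #
# PCA loadings
# ---------------------------------------------------------------------- #
def pca_loading_select(
    cohort, config: SelectorConfig | None = None, features: list[str] | None = None
) -> FeatureSet:
    """Select the features with the greatest influence on the retained components.

    Default ranking: ``sum_c w_c * loading_cj**2`` with
    ``w_c = max(EV_c − λ_bulk, 0)``, where ``λ_bulk = (1 + sqrt(p/n))²`` is
    the Marchenko–Pastur upper bulk edge for standardized data — the largest
    eigenvalue a pure-noise correlation matrix of this shape produces.
    Components whose eigenvalue sits inside the noise bulk therefore carry
    no weight; if *no* component exceeds the edge, plain eigenvalue weights
    are used.  The score is invariant to component sign flips.
    ``pca_allocation="round_robin"`` instead cycles through components in
    explained-variance order, taking the next highest-|loading| unselected
    feature from each.
    """
    config = config or SelectorConfig()
    feats, X, _ = _design(cohort, features)
    if config.pca_n_features > len(feats):
        raise ValueError(f"pca_n_features={config.pca_n_features} exceeds {len(feats)} features")
    n_comp = min(config.pca_components, len(feats), X.shape[0])
    pca = PCA(n_components=n_comp, random_state=config.seed)
    pca.fit(X)
    loadings = np.abs(pca.components_)  # components already in EV order

    if config.pca_allocation == "weighted":
        bulk_edge = (1 + np.sqrt(len(feats) / X.shape[0])) ** 2
        weights = np.clip(pca.explained_variance_ - bulk_edge, 0, None)
        if not weights.any():
            weights = pca.explained_variance_
        score = weights @ (loadings**2)
        order = sorted(range(len(feats)), key=lambda j: (-score[j], feats[j]))
        return FeatureSet("PCA", [feats[j] for j in order[: config.pca_n_features]])

    if config.pca_allocation != "round_robin":
        raise ValueError(f"unknown pca_allocation {config.pca_allocation!r}")
    # per component, feature indices by descending |loading| (name tie-break)
    ranked = [
        sorted(range(len(feats)), key=lambda j: (-loadings[c, j], feats[j]))
        for c in range(n_comp)
    ]
    chosen: list[str] = []
    taken = set()
    cursors = [0] * n_comp
    while len(chosen) < config.pca_n_features:
        for c in range(n_comp):
            if len(chosen) >= config.pca_n_features:
                break
            while cursors[c] < len(feats) and ranked[c][cursors[c]] in taken:
                cursors[c] += 1
            if cursors[c] < len(feats):
                j = ranked[c][cursors[c]]
                taken.add(j)
                chosen.append(feats[j])
                cursors[c] += 1
    return FeatureSet("PCA", chosen)
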