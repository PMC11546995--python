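"""Selector contracts: NB ranking against sklearn and effect-size oracles,
SVC coefficient thresholding, PCA loading selection and its invariances."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC

import panelminer as pm
from panelminer._cohort import Cohort
from panelminer.feature_select import FeatureSet, _nb_scores_one_split


def cohort_from_matrix(X, y, prefix="F"):
    feats = [f"{prefix}{j:02d}" for j in range(X.shape[1])]
    data = pd.DataFrame(
        X, columns=feats, index=pd.Index([f"S{i:03d}" for i in range(len(y))], name="sample_id")
    )
    data["group"] = y
    return Cohort(data, metabolites=tuple(feats), demographics=())


# ----------------------------- FeatureSet ----------------------------- #
def test_feature_set_rejects_duplicates_and_round_trips(tmp_path):
    with pytest.raises(ValueError):
        FeatureSet("bad", ["a", "a"])
    fs = FeatureSet("ok", ["b", "a"])
    fs.to_json(tmp_path / "fs.json")
    back = FeatureSet.from_json(tmp_path / "fs.json")
    assert back == fs and back.members == ("b", "a")


# ----------------------------- NB ------------------------------------- #
def test_nb_vectorised_scores_match_sklearn_gaussian_nb():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (80, 6))
    y = np.array([1] * 40 + [0] * 40)
    X[y == 1, 0] += 1.5
    tr, te = next(StratifiedShuffleSplit(n_splits=1, test_size=0.25, random_state=1).split(X, y))
    acc, f1 = _nb_scores_one_split(X[tr], y[tr], X[te], y[te])
    for j in range(X.shape[1]):
        clf = GaussianNB().fit(X[tr][:, [j]], y[tr])
        assert acc[j] == pytest.approx((clf.predict(X[te][:, [j]]) == y[te]).mean(), abs=1e-12)


def test_nb_ranks_separating_feature_first():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (60, 21))
    y = np.array([1] * 30 + [0] * 30)
    X[:, 7] = np.where(y == 1, 5.0, 0.0) + rng.normal(0, 0.1, 60)
    c = cohort_from_matrix(X, y)
    fs = pm.nb_univariate_select(c, pm.SelectorConfig(nb_top_k=3, nb_n_splits=20, seed=0))
    assert fs.members[0] == "F07"


def test_nb_set_size_contract_on_pure_noise():
    rng = np.random.default_rng(2)
    y = np.array([1] * 25 + [0] * 25)
    for seed in (0, 1):
        X = rng.normal(0, 1, (50, 10))
        c = cohort_from_matrix(X, y)
        fs = pm.nb_univariate_select(c, pm.SelectorConfig(nb_top_k=4, nb_n_splits=25, seed=seed))
        assert len(fs) == 4


def test_nb_ranking_follows_effect_size_ordering():
    """Per-feature Bayes accuracy grows with effect size, so at large n the
    empirical ranking must reproduce the planted 2.0 > 1.0 > 0.0 ordering."""
    rng = np.random.default_rng(3)
    y = np.array([1] * 200 + [0] * 200)
    X = rng.normal(0, 1, (400, 3))
    X[y == 1, 0] += 2.0
    X[y == 1, 1] += 1.0
    c = cohort_from_matrix(X, y)
    fs = pm.nb_univariate_select(c, pm.SelectorConfig(nb_top_k=3, nb_n_splits=50, seed=0))
    assert fs.members == ("F00", "F01", "F02")


def test_nb_top_k_larger_than_pool_fails():
    c = cohort_from_matrix(np.zeros((10, 2)), np.array([1] * 5 + [0] * 5))
    with pytest.raises(ValueError):
        pm.nb_univariate_select(c, pm.SelectorConfig(nb_top_k=5, nb_n_splits=5))


# ----------------------------- SVC ------------------------------------ #
def test_svc_selects_dominant_informative_features():
    rng = np.random.default_rng(4)
    y = np.array([1] * 100 + [0] * 100)
    X = rng.normal(0, 1, (200, 12))
    X[y == 1, 0] += 3.0
    X[y == 1, 1] -= 3.0
    X = (X - X.mean(0)) / X.std(0)
    c = cohort_from_matrix(X, y)
    fs = pm.svc_l2_select(c, pm.SelectorConfig(seed=0))
    assert {"F00", "F01"} <= set(fs.members)


def test_svc_duplicated_columns_get_equal_coefficients():
    rng = np.random.default_rng(5)
    y = np.array([1] * 50 + [0] * 50)
    x = rng.normal(0, 1, 100) + y
    X = np.column_stack([x, x, rng.normal(0, 1, 100)])
    model = LinearSVC(penalty="l2", C=0.001, dual=True, random_state=0, max_iter=20000)
    model.fit(X, y)
    assert abs(model.coef_[0, 0] - model.coef_[0, 1]) < 1e-6


def test_svc_threshold_matches_mean_coefficient_oracle():
    rng = np.random.default_rng(6)
    y = np.array([1] * 60 + [0] * 60)
    X = rng.normal(0, 1, (120, 8))
    X[y == 1, :3] += 1.0
    c = cohort_from_matrix(X, y)
    cfg = pm.SelectorConfig(seed=0)
    fs = pm.svc_l2_select(c, cfg)
    model = LinearSVC(penalty="l2", C=cfg.svc_C, dual=True, random_state=0, max_iter=20000)
    model.fit(X, y)
    coefs = np.abs(model.coef_.ravel())
    expected = {f"F{j:02d}" for j in range(8) if coefs[j] >= coefs.mean()}
    assert set(fs.members) == expected


# ----------------------------- PCA ------------------------------------ #
def test_pca_selects_dominant_variance_block_first():
    rng = np.random.default_rng(7)
    factor = rng.normal(0, 3, 100)
    block = np.column_stack([factor + rng.normal(0, 0.3, 100) for _ in range(5)])
    noise = rng.normal(0, 1, (100, 10))
    X = np.column_stack([block, noise])
    y = np.array([1] * 50 + [0] * 50)
    c = cohort_from_matrix(X, y)
    fs = pm.pca_loading_select(c, pm.SelectorConfig(pca_components=3, pca_n_features=5, seed=0))
    assert set(fs.members) == {f"F{j:02d}" for j in range(5)}


def test_pca_exhaustive_returns_all_features():
    rng = np.random.default_rng(8)
    X = rng.normal(0, 1, (30, 6))
    c = cohort_from_matrix(X, np.array([1] * 15 + [0] * 15))
    fs = pm.pca_loading_select(c, pm.SelectorConfig(pca_components=2, pca_n_features=6))
    assert set(fs.members) == set(c.features)


def test_pca_loadings_match_eigendecomposition_oracle():
    rng = np.random.default_rng(9)
    X = rng.normal(0, 1, (6, 4))
    pca = PCA(n_components=3).fit(X)
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    for k in range(3):
        v = eigvecs[:, order[k]]
        np.testing.assert_allclose(
            np.abs(pca.components_[k]), np.abs(v), atol=1e-8
        )
        assert pca.explained_variance_[k] == pytest.approx(eigvals[order[k]])


def test_pca_selection_invariant_to_sign_flips():
    rng = np.random.default_rng(10)
    X = rng.normal(0, 1, (60, 8))
    y = np.array([1] * 30 + [0] * 30)
    cfg = pm.SelectorConfig(pca_components=3, pca_n_features=4, seed=0)
    a = pm.pca_loading_select(cohort_from_matrix(X, y), cfg)
    b = pm.pca_loading_select(cohort_from_matrix(-X, y), cfg)
    assert a.members == b.members


def test_pca_too_many_features_requested_fails():
    c = cohort_from_matrix(np.zeros((10, 3)), np.array([1] * 5 + [0] * 5))
    with pytest.raises(ValueError):
        pm.pca_loading_select(c, pm.SelectorConfig(pca_components=2, pca_n_features=4))


# ----------------------------- recovery (shared surface) --------------- #
def test_selectors_recover_planted_features(signal_cohort):
    """Each selector recovers >=80% of 10 planted 1.5-SD features (150/arm)."""
    rates = {"nb": [], "svc": [], "pca": []}
    for seed in range(5):
        clean, planted = signal_cohort(seed)
        cfg = pm.SelectorConfig(nb_top_k=15, nb_n_splits=50, pca_n_features=15, seed=seed)
        rates["nb"].append(len(planted & set(pm.nb_univariate_select(clean, cfg).members)) / 10)
        rates["svc"].append(len(planted & set(pm.svc_l2_select(clean, cfg).members)) / 10)
        rates["pca"].append(len(planted & set(pm.pca_loading_select(clean, cfg).members)) / 10)
    for name, values in rates.items():
        assert np.mean(values) >= 0.8, name
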