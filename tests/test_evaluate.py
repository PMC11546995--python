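"""Metric primitives against brute-force oracles, ROC consistency, the
repeated-CV harness (manual re-execution, determinism, null calibration),
and the hyperparameter grid search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

import panelminer as pm
from panelminer._cohort import Cohort
from conftest import brute_force_auc, brute_force_confusion_metrics


def cohort_from_matrix(X, y):
    feats = [f"F{j:02d}" for j in range(X.shape[1])]
    data = pd.DataFrame(
        X, columns=feats, index=pd.Index([f"S{i:03d}" for i in range(len(y))], name="sample_id")
    )
    data["group"] = y
    return Cohort(data, metabolites=tuple(feats), demographics=())


# ----------------------------- metric primitives ----------------------- #
def test_perfect_confusion_metrics():
    m = pm.compute_metrics([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert m["accuracy"] == 1 and m["mcc"] == 1 and m["f1"] == 1 and m["auc"] == 1


def test_degenerate_single_class_prediction_gives_zero_mcc():
    m = pm.compute_metrics([1, 1, 0, 0], [1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5])
    assert m["mcc"] == 0.0
    assert m["auc"] == 0.5


def test_auc_examples_and_pairwise_oracle():
    m = pm.compute_metrics([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1])
    assert m["auc"] == 1.0
    labels = [1, 0, 1, 0]
    scores = [0.9, 0.8, 0.3, 0.1]
    m2 = pm.compute_metrics(labels, [1, 1, 0, 0], scores)
    assert m2["auc"] == pytest.approx(brute_force_auc(labels, scores))


def test_metrics_match_brute_force_on_many_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(120):
        n = rng.integers(6, 30)
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            continue
        preds = rng.integers(0, 2, n)
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces score ties
        m = pm.compute_metrics(labels, preds, scores)
        oracle = brute_force_confusion_metrics(labels, preds)
        for key, val in oracle.items():
            assert m[key] == pytest.approx(val, abs=1e-12), key
        assert m["auc"] == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)


def test_non_binary_labels_rejected():
    with pytest.raises(ValueError):
        pm.compute_metrics([1, 2], [1, 0], [0.5, 0.5])


# ----------------------------- ROC ------------------------------------ #
def test_roc_staircase_and_area_equals_rank_auc():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    scores = np.round(rng.normal(0, 1, 40), 1)
    pts = pm.roc_points(labels, scores)
    assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
    assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
    area = np.trapezoid(pts[:, 1], pts[:, 0])
    assert area == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)


def test_roc_perfect_separation_passes_through_corner():
    pts = pm.roc_points([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
    assert any((p[0] == 0.0 and p[1] == 1.0) for p in pts)


def test_roc_reversed_scores_mirror_area():
    rng = np.random.default_rng(2)
    labels = np.array([1] * 10 + [0] * 10)
    scores = rng.normal(0, 1, 20)
    a = np.trapezoid(*pm.roc_points(labels, scores).T[::-1])
    b = np.trapezoid(*pm.roc_points(labels, -scores).T[::-1])
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    labels = np.array([1] * 15 + [0] * 15)
    scores = rng.normal(0, 1, 30)
    a = pm.compute_metrics(labels, labels, scores)["auc"]
    b = pm.compute_metrics(labels, labels, np.exp(3 * scores))["auc"]
    assert a == pytest.approx(b, abs=1e-12)


# ----------------------------- repeated CV ----------------------------- #
def separable_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.normal(0, 1, (n, 3))
    X[y == 1, 0] += 6.0
    return cohort_from_matrix(X, y)


def test_repeated_cv_perfect_on_separable_data():
    c = separable_cohort()
    summary = pm.repeated_cv_eval(c, ["F00"], pm.EvalConfig(n_folds=5, n_repeats=2, seed=0))
    assert summary.auc == pytest.approx(1.0)
    assert summary.accuracy > 0.95
    assert summary.auc_ci[0] <= summary.auc <= summary.auc_ci[1]


def test_repeated_cv_is_deterministic_under_fixed_seed():
    c = separable_cohort(seed=4)
    cfg = pm.EvalConfig(n_folds=4, n_repeats=2, seed=9)
    a = pm.repeated_cv_eval(c, c.features, cfg)
    b = pm.repeated_cv_eval(c, c.features, cfg)
    pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)


def test_repeated_cv_null_calibration_on_permuted_labels():
    rng = np.random.default_rng(5)
    X = rng.normal(0, 1, (300, 5))
    y = rng.permutation([1] * 150 + [0] * 150)
    c = cohort_from_matrix(X, y)
    summary = pm.repeated_cv_eval(c, c.features, pm.EvalConfig(n_folds=10, n_repeats=3, seed=0))
    assert abs(summary.auc - 0.5) < 0.05


def test_repeated_cv_matches_manual_fold_re_execution():
    """Step-by-step re-run of the identical partitions with sklearn pieces."""
    c = separable_cohort(n=40, seed=6)
    feats = list(c.features)
    cfg = pm.EvalConfig(n_folds=3, n_repeats=2, seed=13)
    summary = pm.repeated_cv_eval(c, feats, cfg)

    X = c.data[feats].to_numpy(float)
    y = c.labels
    rows = []
    splitter = RepeatedStratifiedKFold(n_splits=3, n_repeats=2, random_state=13)
    for tr, te in splitter.split(X, y):
        mean, sd = X[tr].mean(0), X[tr].std(0, ddof=0)
        Xtr = (X[tr] - mean) / sd
        Xte = (X[te] - mean) / sd
        clf = SVC(C=5.0, kernel="rbf", gamma="scale", class_weight="balanced").fit(Xtr, y[tr])
        rows.append(
            pm.compute_metrics(y[te], clf.predict(Xte), clf.decision_function(Xte))
        )
    manual = pd.DataFrame(rows)
    pd.testing.assert_frame_equal(summary.fold_metrics, manual)


def test_cv_standardization_is_fit_per_training_fold():
    """An extreme outlier in one sample must not shift other folds' scalers:
    fold metrics on folds excluding the outlier are unchanged."""
    c = separable_cohort(n=30, seed=7)
    cfg = pm.EvalConfig(n_folds=3, n_repeats=1, seed=1)
    base = pm.repeated_cv_eval(c, c.features, cfg).fold_metrics

    data = c.data.copy()
    data.loc["S000", "F01"] = 1e6  # only folds containing S000 may change
    modified = pm.repeated_cv_eval(
        Cohort(data, c.metabolites, ()), c.features, cfg
    ).fold_metrics
    splitter = RepeatedStratifiedKFold(n_splits=3, n_repeats=1, random_state=1)
    X = c.data[c.features].to_numpy(float)
    for i, (tr, te) in enumerate(splitter.split(X, c.labels)):
        if 0 not in tr and 0 not in te:
            pd.testing.assert_series_equal(base.iloc[i], modified.iloc[i])


# ----------------------------- grid search ----------------------------- #
def test_single_point_grid_returns_that_point():
    c = separable_cohort(n=30, seed=8)
    cfg = pm.EvalConfig(
        c_grid=(0.5,), kernels=("rbf",), gamma_modes=("scale",),
        n_folds=3, n_repeats=1, seed=0,
    )
    chosen, scores = pm.grid_search_svc(c, c.features, cfg)
    assert (chosen["C"], chosen["kernel"], chosen["gamma"]) == (0.5, "rbf", "scale")
    assert len(scores) == 1


def test_grid_search_finds_perfect_auc_on_separable_toy():
    c = separable_cohort(n=40, seed=9)
    cfg = pm.EvalConfig(n_folds=3, n_repeats=1, seed=0)
    chosen, scores = pm.grid_search_svc(c, ["F00"], cfg)
    assert scores["auc"].max() == pytest.approx(1.0)
    assert chosen["auc"] == pytest.approx(1.0)


def test_grid_argmax_matches_independent_re_scoring():
    c = separable_cohort(n=30, seed=10)
    cfg = pm.EvalConfig(
        c_grid=(0.05, 5.0), kernels=("linear", "rbf"), gamma_modes=("scale",),
        n_folds=3, n_repeats=1, seed=2,
    )
    chosen, scores = pm.grid_search_svc(c, c.features, cfg)
    assert len(scores) == 4
    best_auc = scores["auc"].max()
    ties = scores[scores["auc"] == best_auc]
    # deterministic tie-break: highest C, then kernel order as listed
    expected = ties.sort_values(
        ["C", "kernel"],
        key=lambda s: -s if s.name == "C" else s.map({"linear": 0, "rbf": 1}),
    ).iloc[0]
    assert chosen["C"] == expected["C"] and chosen["kernel"] == expected["kernel"]


def test_empty_grid_rejected():
    c = separable_cohort(n=20, seed=11)
    with pytest.raises(ValueError):
        pm.grid_search_svc(c, c.features, pm.EvalConfig(c_grid=()))
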