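import numpy as np
import pytest

import panelminer as pm


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference study design: 185/53, 138 metabolites, 6 sparse columns."""
    return pm.generate_cohort(pm.SimConfig(seed=11))


@pytest.fixture(scope="session")
def clean_reference(reference_cohort):
    clean, report = pm.run_preprocess(reference_cohort)
    return clean, report


def make_signal_cohort(
    seed: int,
    n_per_arm: int = 150,
    n_features: int = 30,
    n_planted: int = 10,
    effect: float = 1.5,
    demographics: bool = False,
):
    """Metabolite-only cohort with the first ``n_planted`` features planted."""
    names = tuple(f"Met{i:03d}" for i in range(101, 101 + n_features))
    planted = tuple((names[i], effect) for i in range(n_planted))
    cfg = pm.SimConfig(
        n_cases=n_per_arm,
        n_controls=n_per_arm,
        n_metabolites=n_features,
        feature_names=names,
        planted_features=planted,
        sparse_features=(),
        missing_rate=0.0,
        age_effect=0.0,
        seed=seed,
    )
    cohort = pm.generate_cohort(cfg)
    if not demographics:
        cohort = pm.Cohort(
            cohort.data.drop(columns=["race", "smoking", "age", "BMI"]),
            cohort.metabolites,
            (),
        )
    clean, _ = pm.run_preprocess(cohort)
    return clean, set(f for f, _ in planted)


@pytest.fixture
def signal_cohort():
    return make_signal_cohort


def brute_force_auc(labels, scores) -> float:
    """All-pairs rank AUC oracle: P(case score > control score), ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_confusion_metrics(labels, predictions) -> dict:
    """Confusion-matrix oracle for accuracy / precision / recall / F1 / MCC."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    tp = int(((predictions == 1) & (labels == 1)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "accuracy": (tp + tn) / len(labels),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }
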