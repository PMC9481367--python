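"""Classification metrics and the baseline-model comparison harness."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from pathsparse.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    accuracy: float
    auc: float
    aupr: float
    f1: float
    precision: float
    recall: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "aupr": self.aupr,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "threshold": self.threshold,
        }


def compute_metrics(y, p, threshold: float = 0.5, y_pred=None) -> MetricsReport:
    """Thresholded and threshold-free metrics with class 1 as positive.

    ``p`` can be probabilities or arbitrary monotone scores (AUC/AUPR only
    depend on the ordering).  ``y_pred`` overrides the thresholded
    predictions when a classifier's own decision rule should be used.
    AUPR uses step interpolation of precision (average-precision convention).
    """
    y = np.asarray(y, dtype=int).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {p.shape}")
    pred = np.asarray(y_pred, dtype=int).ravel() if y_pred is not None else (p >= threshold).astype(int)

    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    accuracy = (tp + tn) / len(y)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0

    if len(np.unique(y)) < 2:
        logger.warning("single-class labels: AUC/AUPR undefined")
        auc = aupr = float("nan")
    else:
        if np.ptp(p) == 0:
            logger.info("constant scores: AUC falls to 0.5 by midrank convention")
        auc = float(roc_auc_score(y, p))
        aupr = float(average_precision_score(y, p))
    return MetricsReport(
        accuracy=float(accuracy),
        auc=auc,
        aupr=aupr,
        f1=float(f1),
        precision=float(precision),
        recall=float(recall),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        threshold=threshold,
    )


BASELINE_FACTORIES = {
    "logistic_regression_l2": lambda seed: LogisticRegression(random_state=seed),
    "svm_rbf": lambda seed: SVC(kernel="rbf", random_state=seed),
    "svm_linear": lambda seed: SVC(kernel="linear", random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
}


def run_baselines(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the classic baseline families at library defaults; one row per model.

    All baselines consume the same binary feature matrix as the network.
    Probability scores come from ``predict_proba`` when available, otherwise
    from the decision function; thresholded metrics use each model's own
    ``predict``.
    """
    rows = {}
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training fold has a single class")
    for name, factory in BASELINE_FACTORIES.items():
        clf = factory(seed)
        clf.fit(x_train, y_train)
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(x_test)[:, 1]
        else:
            scores = clf.decision_function(x_test)
        report = compute_metrics(y_test, scores, y_pred=clf.predict(x_test))
        rows[name] = report.to_dict()
    return pd.DataFrame.from_dict(rows, orient="index")
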