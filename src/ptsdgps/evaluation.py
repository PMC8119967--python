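"""Performance metrics for the final ensemble probabilities.

Reports the quantities the classification analysis is judged on: ROC curve
and AUC, the Youden-optimal ("balanced") sensitivity/specificity pair and
their mean (balanced accuracy), raw accuracy, and Cohen's kappa.

Conventions: Group 1 (PTSD) is the positive class; a subject is classified
positive when its probability is strictly greater than the threshold.
Balanced metrics are read off the ROC at the threshold maximizing Youden's
J = sensitivity + specificity − 1 (ties broken toward the most balanced
sensitivity/specificity pair); raw accuracy and kappa are reported at the
fixed 0.5 threshold, the common default of classification toolkits. Both
thresholds appear in the report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .learners import POSITIVE_GROUP


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class PerformanceReport:
    auc: float
    accuracy: float
    balanced_sensitivity: float
    balanced_specificity: float
    balanced_accuracy: float
    kappa: float
    chosen_threshold: float
    accuracy_threshold: float = 0.5
    positive_class: str = "group 1 (PTSD)"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def __str__(self) -> str:
        return (
            f"AUC = {self.auc:.3f}\n"
            f"accuracy = {self.accuracy:.3f} (threshold {self.accuracy_threshold})\n"
            f"balanced sensitivity = {self.balanced_sensitivity:.3f}\n"
            f"balanced specificity = {self.balanced_specificity:.3f}\n"
            f"balanced accuracy = {self.balanced_accuracy:.3f}\n"
            f"Cohen's kappa = {self.kappa:.3f}\n"
            f"balanced threshold = {self.chosen_threshold:.3f} "
            f"(positive class: {self.positive_class})"
        )


def _to_binary(labels) -> np.ndarray:
    """Map group labels {1, 2} (or already-binary {0, 1}) to 1 = positive."""
    y = np.asarray(labels)
    if set(np.unique(y)) <= {0, 1}:
        return y.astype(int)
    return (y == POSITIVE_GROUP).astype(int)


def roc_auc(probabilities, labels) -> RocCurve:
    """ROC by sweeping all distinct probabilities; AUC via rank statistic.

    The AUC equals the Mann–Whitney probability that a random positive
    outscores a random negative, ties counting one half.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    # candidate thresholds: below the minimum, then every distinct score
    distinct = np.unique(p)
    thresholds = np.concatenate([[distinct[0] - 1.0], distinct])
    sens = np.array([np.mean(p[y == 1] > t) for t in thresholds])
    spec = np.array([np.mean(p[y == 0] <= t) for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(roc_auc_score(y, p)),
    )


def optimal_threshold(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J; returns (threshold, sens, spec).

    Ties on J are broken toward the most balanced operating point
    (smallest |sensitivity − specificity|).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(np.isclose(j, best_j))
    imbalance = np.abs(roc.sensitivity[candidates] - roc.specificity[candidates])
    i = candidates[int(np.argmin(imbalance))]
    return float(roc.thresholds[i]), float(roc.sensitivity[i]), float(roc.specificity[i])


def confusion_metrics(probabilities, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) classifying positive at prob > threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = _to_binary(labels)
    pred = (p > threshold).astype(int)
    tp = np.sum((pred == 1) & (y == 1))
    tn = np.sum((pred == 0) & (y == 0))
    fp = np.sum((pred == 1) & (y == 0))
    fn = np.sum((pred == 0) & (y == 1))
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / len(y)
    return float(sens), float(spec), float(acc)


def balanced_accuracy(sens: float, spec: float) -> float:
    """Mean of sensitivity and specificity."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sens + spec) / 2.0


def cohens_kappa(predicted_classes, labels) -> float:
    """Chance-corrected agreement between predicted and true classes."""
    pred = _to_binary(predicted_classes)
    y = _to_binary(labels)
    if len(pred) != len(y):
        raise ValueError("length mismatch")
    if len(np.unique(np.concatenate([pred, y]))) < 2:
        return 0.0  # degenerate marginals: p_e = 1
    return float(cohen_kappa_score(y, pred))


def evaluate(probabilities, labels, accuracy_threshold: float = 0.5) -> PerformanceReport:
    """Full performance report from final out-of-fold probabilities."""
    roc = roc_auc(probabilities, labels)
    thr, sens, spec = optimal_threshold(roc)
    _, _, acc = confusion_metrics(probabilities, labels, accuracy_threshold)
    p = np.asarray(probabilities, dtype=float)
    pred = (p > accuracy_threshold).astype(int)
    kappa = cohens_kappa(pred, labels)
    return PerformanceReport(
        auc=roc.auc,
        accuracy=acc,
        balanced_sensitivity=sens,
        balanced_specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        kappa=kappa,
        chosen_threshold=thr,
        accuracy_threshold=accuracy_threshold,
    )


def roc_to_frame(roc: RocCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": roc.thresholds, "sensitivity": roc.sensitivity, "specificity": roc.specificity}
    )
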