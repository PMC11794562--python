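"""Multi-class evaluation: confusion matrices, one-vs-rest metrics, ROC/AUC.

Per-class precision, sensitivity (recall), specificity and F1 come from
the one-vs-rest reduction of the confusion matrix:

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Overall accuracy is trace/total (the multi-class reading of
(TP+TN)/(TP+TN+FP+FN), to which it reduces for two classes).  Macro
averages are unweighted means over classes.  AUC uses the rank
(pairwise-probability) definition with ties counted one half.  Ratios of
the form 0/0 are reported as 0 and flagged, so macro averages stay
computable on degenerate splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_CLASSES = ("N", "S", "V")


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class ClassMetrics:
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float | None = None
    undefined: tuple[str, ...] = field(default_factory=tuple)


def confusion(y_true, y_pred, classes=DEFAULT_CLASSES) -> ConfusionMatrix:
    """Count (true, predicted) label pairs over the fixed class order."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    lut = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(yt, yp):
        if str(t) not in lut or str(p) not in lut:
            raise ValueError(f"label outside class set {classes}: {t!r}/{p!r}")
        counts[lut[str(t)], lut[str(p)]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest precision/sensitivity/specificity/F1 for one class."""
    c = cm.classes.index(cls)
    counts = cm.counts
    tp = counts[c, c]
    fn = counts[c].sum() - tp
    fp = counts[:, c].sum() - tp
    tn = counts.sum() - tp - fn - fp
    flags: list[str] = []
    precision = _safe_div(tp, tp + fp, "precision", flags)
    sensitivity = _safe_div(tp, tp + fn, "sensitivity", flags)
    specificity = _safe_div(tn, tn + fp, "specificity", flags)
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity,
                   "f1", flags)
    return ClassMetrics(precision, sensitivity, specificity, f1,
                        undefined=tuple(flags))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified beats: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix has no accuracy")
    return float(np.trace(cm.counts)) / cm.total


def macro_average(per_class: list[ClassMetrics]) -> ClassMetrics:
    """Unweighted mean of each metric over classes."""
    if not per_class:
        raise ValueError("no per-class metrics to average")
    aucs = [m.auc for m in per_class]
    return ClassMetrics(
        precision=float(np.mean([m.precision for m in per_class])),
        sensitivity=float(np.mean([m.sensitivity for m in per_class])),
        specificity=float(np.mean([m.specificity for m in per_class])),
        f1=float(np.mean([m.f1 for m in per_class])),
        auc=None if any(a is None for a in aucs) else float(np.mean(aucs)),
    )


def roc_auc(y_true, scores, cls: str) -> float:
    """One-vs-rest AUC by the rank definition; ties count one half.

    Equals the probability that a random positive outranks a random
    negative.  Raises if the class is absent (or universal) in ``y_true``.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = yt == cls
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"AUC undefined: class {cls!r} has "
                         f"{n_pos} positives / {n_neg} negatives")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(y_true, y_pred, probs=None,
             classes=DEFAULT_CLASSES) -> dict:
    """Full report: confusion matrix, per-class metrics, macro row, accuracy.

    ``probs`` (n x K class probabilities, columns in class order) adds AUC.
    """
    cm = confusion(y_true, y_pred, classes)
    per_class = {}
    for i, cls in enumerate(classes):
        m = class_metrics(cm, cls)
        if probs is not None:
            try:
                m.auc = roc_auc(y_true, np.asarray(probs)[:, i], cls)
            except ValueError:
                m.undefined = m.undefined + ("auc",)
        per_class[cls] = m
    return {
        "confusion": cm,
        "per_class": per_class,
        "macro": macro_average(list(per_class.values())),
        "accuracy": overall_accuracy(cm),
    }


def report_frame(results: dict) -> pd.DataFrame:
    """Tabular report with per-class rows and a macro-average row.

    Ratio metrics are rendered as percentages to two decimals; AUC stays
    on [0, 1].
    """
    rows = []
    items = list(results["per_class"].items()) + [("Macro average",
                                                   results["macro"])]
    for name, m in items:
        rows.append({
            "class": name,
            "precision_pct": round(100 * m.precision, 2),
            "sensitivity_pct": round(100 * m.sensitivity, 2),
            "specificity_pct": round(100 * m.specificity, 2),
            "f1_pct": round(100 * m.f1, 2),
            "auc": None if m.auc is None else round(m.auc, 2),
        })
    frame = pd.DataFrame(rows)
    frame.attrs["accuracy_pct"] = round(100 * results["accuracy"], 2)
    return frame
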