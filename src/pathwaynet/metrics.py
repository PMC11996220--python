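"""Multiclass evaluation: per-class contingency counts, accuracy,
precision, recall, F1 and one-vs-rest AUC, with macro averages.

Per-class counts follow the one-vs-rest convention: for class c, TP are
class-c samples predicted c, TN are non-c samples predicted non-c, FP are
non-c samples predicted c, and FN are class-c samples predicted non-c.
Precision is TP/(TP+FP); recall TP/(TP+FN); F1 their harmonic mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .cohort import CLASS_ORDER

__all__ = ["MetricsReport", "evaluate_predictions"]


@dataclass
class MetricsReport:
    confusion: np.ndarray  # rows true, cols predicted, CN/MCI/AD order
    per_class: pd.DataFrame  # index CN/MCI/AD: tp tn fp fn accuracy precision recall f1 auc
    accuracy: float  # micro accuracy = trace / n
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    n: int
    undefined_auc: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "undefined_auc": self.undefined_auc,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(
    y_true: np.ndarray, proba: np.ndarray
) -> MetricsReport:
    """Score class-probability predictions against integer labels (CN=0,
    MCI=1, AD=2).

    AUC is one-vs-rest per class from the softmax scores; a class absent
    from ``y_true`` gets NaN AUC and is excluded from the macro average.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    y_pred = proba.argmax(axis=1)
    n = len(y_true)
    labels = [0, 1, 2]
    cm = confusion_matrix(y_true, y_pred, labels=labels)

    rows = {}
    undefined = []
    for c, name in enumerate(CLASS_ORDER):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        if (y_true == c).any() and not (y_true == c).all():
            auc = roc_auc_score((y_true == c).astype(int), proba[:, c])
        else:
            auc = np.nan
            undefined.append(name)
        rows[name] = {
            "tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn),
            "accuracy": (tp + tn) / n,
            "precision": precision, "recall": recall, "f1": f1, "auc": auc,
        }
    per_class = pd.DataFrame(rows).T
    aucs = per_class["auc"].dropna()
    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        accuracy=float(np.trace(cm) / n),
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        macro_auc=float(aucs.mean()) if len(aucs) else float("nan"),
        n=n,
        undefined_auc=undefined,
    )
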