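"""Deterministic evaluation: confusion matrix and per-class ACC / PPV / NPV.

Metrics are computed one-vs-rest per class from TP/FP/TN/FN counts:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    PPV = TP / (TP + FP)        NPV = TN / (TN + FN)

Undefined ratios (zero denominators) are reported as ``None``, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """ACC/PPV/NPV from a one-vs-rest contingency; None when undefined."""
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty contingency")
    return {
        "acc": (tp + tn) / total,
        "ppv": tp / (tp + fp) if tp + fp > 0 else None,
        "npv": tn / (tn + fn) if tn + fn > 0 else None,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics."""

    confusion: np.ndarray
    class_names: tuple
    per_class: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def macro(self, metric: str) -> float:
        vals = [m[metric] for m in self.per_class.values()
                if m[metric] is not None]
        return float(np.mean(vals)) if vals else float("nan")


def report_from_predictions(y_true, y_pred, class_names=None,
                            metadata: dict | None = None) -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty dataset")
    if class_names is None:
        class_names = tuple(np.unique(np.concatenate([y_true, y_pred])))
    names = list(class_names)
    K = len(names)
    idx = {c: i for i, c in enumerate(names)}
    conf = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    per_class = {}
    total = conf.sum()
    for i, name in enumerate(names):
        tp = int(conf[i, i])
        fn = int(conf[i].sum() - tp)
        fp = int(conf[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        per_class[name] = metrics_from_counts(tp, fp, tn, fn)
    return EvalReport(confusion=conf, class_names=tuple(names),
                      per_class=per_class, metadata=metadata or {})


def evaluate(clf, X, y, metadata: dict | None = None) -> EvalReport:
    """Evaluate a fitted classifier deterministically (greedy actions,
    mean glimpse locations)."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty dataset")
    y_pred = clf.predict(np.asarray(X, dtype=float))
    return report_from_predictions(y, y_pred,
                                   class_names=tuple(clf.classes_),
                                   metadata=metadata)
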