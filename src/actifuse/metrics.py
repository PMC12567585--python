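"""Binary-classification metric suite: accuracy, precision, recall, F1,
trapezoidal ROC-AUC (midrank tie handling) and Matthews correlation.

Degenerate denominators follow the documented convention of returning 0 with a
warning rather than raising, so cross-validation folds with single-class
predictions still aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "compute_metrics", "roc_auc", "aggregate_reports"]

METRIC_NAMES = ("precision", "recall", "f1", "accuracy", "auc", "mcc")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator; returning 0 by convention")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and MCC from a confusion table."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (tp + tn) / counts.total
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "mcc": mcc}


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the trapezoidal rule over all thresholds.

    Tied scores are collapsed into single threshold steps, which makes the
    trapezoidal area identical to the midrank (Mann-Whitney) statistic
    U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative TP/FP after each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricsReport:
    """Per-fold metric rows plus mean +/- sd aggregate, one per model/fusion."""

    name: str
    folds: list = field(default_factory=list)   # list of dicts with METRIC_NAMES
    failed_folds: list = field(default_factory=list)

    def add_fold(self, metrics: dict):
        self.folds.append({k: float(metrics[k]) for k in METRIC_NAMES if k in metrics})

    def mean(self) -> dict:
        return {k: float(np.mean([f[k] for f in self.folds])) for k in METRIC_NAMES
                if self.folds and k in self.folds[0]}

    def sd(self) -> dict:
        out = {}
        for k in METRIC_NAMES:
            if not self.folds or k not in self.folds[0]:
                continue
            vals = [f[k] for f in self.folds]
            # identical folds give exactly 0, not floating-point dust
            out[k] = 0.0 if len(vals) < 2 or max(vals) == min(vals) \
                else float(np.std(vals, ddof=1))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per fold plus a `mean +/- sd` aggregate row."""
        rows = [dict(fold=i + 1, **f) for i, f in enumerate(self.folds)]
        frame = pd.DataFrame(rows)
        if self.folds:
            mu, sd = self.mean(), self.sd()
            agg = {"fold": "mean±sd"}
            agg.update({k: f"{mu[k]:.3f}±{sd[k]:.3f}" for k in mu})
            frame = pd.concat([frame, pd.DataFrame([agg])], ignore_index=True)
        return frame

    def to_dict(self) -> dict:
        return {"name": self.name, "folds": self.folds, "mean": self.mean(),
                "sd": self.sd(), "failed_folds": self.failed_folds}


def aggregate_reports(reports) -> pd.DataFrame:
    """One summary row per report (fusion kind), matching the comparison-table
    column layout: Precision, Recall, F1, Accuracy, AUC, MCC."""
    rows = []
    for rep in reports:
        mu, sd = rep.mean(), rep.sd()
        row = {"model": rep.name}
        row.update({k: f"{mu.get(k, float('nan')):.3f}±{sd.get(k, 0.0):.3f}" for k in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
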