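"""Multiclass evaluation: confusion matrix, derived metrics, one-vs-rest ROC.

Per class the one-vs-rest counts TP, TN, FP, FN come straight from the
confusion matrix; then

* accuracy  = (TP + TN) / (TP + TN + FP + FN)   (per class; overall = trace/total)
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)
* F1        = 2 TP / (2 TP + FP + FN)

aggregated macro (unweighted mean over classes) or weighted (by class
support).  ROC curves sweep thresholds over the class's score column
(ties grouped at one threshold); AUC by the trapezoid rule.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "confusion_matrix",
    "classification_metrics",
    "roc_curve_ovr",
    "roc_auc_ovr",
    "EvalReport",
    "evaluate_predictions",
]


def confusion_matrix(y_true, y_pred, n_classes: int = 5) -> np.ndarray:
    """counts[i, j] = number of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    if len(y_true) and (
        y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _ovr_counts(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    total = int(cm.sum())
    tp = int(cm[c, c])
    fp = int(cm[:, c].sum()) - tp
    fn = int(cm[c, :].sum()) - tp
    tn = total - tp - fp - fn
    return tp, tn, fp, fn


def classification_metrics(cm: np.ndarray, average: str = "macro") -> dict:
    """Accuracy, precision, recall, F1 (fractions in [0, 1]).

    Per-class one-vs-rest rates plus the requested aggregate.  A class
    with TP + FP = 0 gets precision 0 (noted in the output).
    """
    cm = np.asarray(cm)
    if average not in ("macro", "weighted"):
        raise ValueError("average must be 'macro' or 'weighted'")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.shape[0]
    per = {"precision": [], "recall": [], "f1": [], "accuracy": []}
    notes = []
    for c in range(n):
        tp, tn, fp, fn = _ovr_counts(cm, c)
        if tp + fp == 0:
            notes.append(f"class {c}: no predicted positives; precision set to 0")
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        per["precision"].append(prec)
        per["recall"].append(rec)
        per["f1"].append(f1)
        per["accuracy"].append((tp + tn) / total)
    support = cm.sum(axis=1)
    if average == "macro":
        w = np.ones(n) / n
    else:
        w = support / support.sum()
    agg = {k: float(np.dot(w, v)) for k, v in per.items() if k != "accuracy"}
    return {
        "accuracy": float(np.trace(cm) / total),
        "precision": agg["precision"],
        "recall": agg["recall"],
        "f1": agg["f1"],
        "per_class": {k: [float(x) for x in v] for k, v in per.items()},
        "support": support.tolist(),
        "average": average,
        "notes": notes,
    }


def roc_curve_ovr(y_true, scores, positive_class: int) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points for one class's score column, ties grouped."""
    y_true = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim == 2:
        s = s[:, positive_class]
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"class {positive_class} absent from one side; ROC undefined")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep the last point of each tied-score run
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def roc_auc_ovr(y_true, probabilities) -> dict:
    """Per-class one-vs-rest AUCs + macro and micro aggregates.

    Classes absent from ``y_true`` get ``nan`` and are excluded from the
    macro mean.  Micro-average pools all (sample, class) indicator pairs.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(probabilities, dtype=np.float64)
    n_classes = p.shape[1]
    aucs, curves = [], {}
    for c in range(n_classes):
        try:
            fpr, tpr = roc_curve_ovr(y_true, p, c)
        except ValueError:
            aucs.append(math.nan)
            continue
        curves[c] = (fpr, tpr)
        aucs.append(float(np.trapezoid(tpr, fpr)))
    valid = [a for a in aucs if not math.isnan(a)]
    # micro: pool the one-vs-rest indicator problems of all classes
    y_bin = np.zeros_like(p, dtype=bool)
    y_bin[np.arange(len(y_true)), y_true] = True
    order = np.argsort(-p.ravel(), kind="stable")
    yb = y_bin.ravel()[order]
    sb = p.ravel()[order]
    tps = np.cumsum(yb)
    fps = np.cumsum(~yb)
    distinct = np.r_[np.diff(sb) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(yb.sum(), 1)]
    fpr = np.r_[0.0, fps[distinct] / max((~yb).sum(), 1)]
    micro = float(np.trapezoid(tpr, fpr))
    return {
        "per_class": aucs,
        "macro": float(np.mean(valid)) if valid else math.nan,
        "micro": micro,
        "curves": curves,
    }


@dataclasses.dataclass
class EvalReport:
    """Everything a scoring run produces, metrics reported in percent."""

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict
    auc: dict

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy_pct": round(self.accuracy, 2),
            "precision_pct": round(self.precision, 2),
            "recall_pct": round(self.recall, 2),
            "f1_pct": round(self.f1, 2),
            "per_class": self.per_class,
            "auc_per_class": [
                None if math.isnan(a) else round(a, 4) for a in self.auc["per_class"]
            ],
            "auc_macro": None if math.isnan(self.auc["macro"]) else round(self.auc["macro"], 4),
            "auc_micro": round(self.auc["micro"], 4),
        }


def evaluate_predictions(
    y_true, probabilities, n_classes: int = 5, average: str = "macro"
) -> EvalReport:
    """Score predicted probability rows against integer labels."""
    p = np.asarray(probabilities, dtype=np.float64)
    y_pred = p.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, n_classes)
    m = classification_metrics(cm, average=average)
    auc = roc_auc_ovr(y_true, p)
    return EvalReport(
        confusion=cm,
        accuracy=100.0 * m["accuracy"],
        precision=100.0 * m["precision"],
        recall=100.0 * m["recall"],
        f1=100.0 * m["f1"],
        per_class=m["per_class"],
        auc=auc,
    )
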