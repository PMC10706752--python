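"""Binary classification metric battery for the tile classifier.

Everything that can be derived from a 2x2 confusion matrix is computed with
explicit closed-form expressions (accuracy, per-class precision/recall/F1
with macro and weighted averages, balanced accuracy, MCC, Cohen's kappa,
Jaccard of the positive class, specificity/sensitivity, Youden's J, G-mean).
Score-dependent metrics (Brier, log loss, ROC/AUC) require per-sample
positive-class probabilities and are never inferred from counts alone.

Class convention: 0 = non-recurring (negative), 1 = recurring (positive).
Zero-denominator rates are reported as 0.0 (and MCC as 0.0 when a marginal
vanishes), matching the usual classification-report convention.

The module can also reconstruct the confusion matrix behind a printed
classification report from the per-class supports and recalls — useful for
checking published reports whose raw predictions are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

LOG_LOSS_EPS = 1e-15

__all__ = [
    "ConfusionMatrix2x2",
    "MetricsReport",
    "confusion_from_predictions",
    "reconstruct_confusion_from_report",
    "compute_metrics",
    "roc_curve",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts indexed [actual][predicted]; class 1 is the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def support(self) -> tuple[int, int]:
        return (self.tn + self.fp, self.fn + self.tp)

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    @classmethod
    def from_array(cls, arr) -> "ConfusionMatrix2x2":
        arr = np.asarray(arr)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 array")
        return cls(tn=int(arr[0, 0]), fp=int(arr[0, 1]),
                   fn=int(arr[1, 0]), tp=int(arr[1, 1]))


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix2x2:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must lie in {0, 1}")
    return ConfusionMatrix2x2(
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
    )


def reconstruct_confusion_from_report(support_0: int, recall_0: float,
                                      support_1: int, recall_1: float,
                                      tol: float = 1e-6) -> ConfusionMatrix2x2:
    """Invert a printed binary classification report back to its counts.

    In the binary case every error of one class lands in the other, so the
    diagonal is recall*support per class and the off-diagonal the remainder.
    The products must be integral (within ``tol``) or the report is
    ambiguous, e.g. from rounded recalls.
    """
    diags = []
    for support, recall in ((support_0, recall_0), (support_1, recall_1)):
        if support < 0:
            raise ValueError("support must be non-negative")
        product = recall * support
        nearest = round(product)
        if abs(product - nearest) > tol:
            raise ValueError(
                f"recall x support = {product!r} is not an integer; "
                f"nearest candidates {math.floor(product)} and {math.ceil(product)} "
                "make the report ambiguous")
        diags.append(int(nearest))
    return ConfusionMatrix2x2(tn=diags[0], fp=support_0 - diags[0],
                              fn=support_1 - diags[1], tp=diags[1])


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


@dataclass
class MetricsReport:
    accuracy: float
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    support: tuple[int, int]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    balanced_accuracy: float
    mcc: float
    cohens_kappa: float
    jaccard: float
    specificity: float
    sensitivity: float
    youden_j: float
    g_mean: float
    brier: float | None = None
    log_loss: float | None = None
    roc_auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form at fixed precision, as printed reports use."""
        out = {}
        for k, v in self.to_dict().items():
            if isinstance(v, float):
                out[k] = round(v, ndigits)
            elif isinstance(v, tuple):
                out[k] = tuple(round(x, ndigits) if isinstance(x, float) else x
                               for x in v)
            else:
                out[k] = v
        return out


def compute_metrics(cm: ConfusionMatrix2x2,
                    scores: np.ndarray | None = None,
                    y_true: np.ndarray | None = None) -> MetricsReport:
    """Full metric battery from counts, plus score metrics when available.

    ``scores`` are per-sample positive-class probabilities aligned with
    ``y_true``; Brier, log loss and AUC stay ``None`` without them.
    """
    tn, fp, fn, tp = cm.tn, cm.fp, cm.fn, cm.tp
    n = cm.total
    prec0 = _safe_div(tn, tn + fn)
    prec1 = _safe_div(tp, tp + fp)
    rec0 = _safe_div(tn, tn + fp)
    rec1 = _safe_div(tp, tp + fn)
    f1_0 = _safe_div(2 * prec0 * rec0, prec0 + rec0)
    f1_1 = _safe_div(2 * prec1 * rec1, prec1 + rec1)
    s0, s1 = cm.support

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, math.sqrt(denom)) if denom else 0.0

    p_o = (tp + tn) / n
    p_e = ((s0 * (tn + fn)) + (s1 * (fp + tp))) / (n * n)
    kappa = _safe_div(p_o - p_e, 1.0 - p_e) if p_e != 1.0 else 0.0

    report = MetricsReport(
        accuracy=p_o,
        precision=(prec0, prec1),
        recall=(rec0, rec1),
        f1=(f1_0, f1_1),
        support=(s0, s1),
        macro_precision=(prec0 + prec1) / 2,
        macro_recall=(rec0 + rec1) / 2,
        macro_f1=(f1_0 + f1_1) / 2,
        weighted_precision=_safe_div(s0 * prec0 + s1 * prec1, n),
        weighted_recall=_safe_div(s0 * rec0 + s1 * rec1, n),
        weighted_f1=_safe_div(s0 * f1_0 + s1 * f1_1, n),
        balanced_accuracy=(rec0 + rec1) / 2,
        mcc=mcc,
        cohens_kappa=kappa,
        jaccard=_safe_div(tp, tp + fp + fn),
        specificity=rec0,
        sensitivity=rec1,
        youden_j=rec1 + rec0 - 1.0,
        g_mean=math.sqrt(rec0 * rec1),
    )

    if scores is not None:
        if y_true is None:
            raise ValueError("score metrics require y_true alongside scores")
        scores = np.asarray(scores, dtype=float)
        y = np.asarray(y_true)
        if scores.shape != y.shape:
            raise ValueError("scores and y_true must align")
        report.brier = float(np.mean((scores - y) ** 2))
        p_true = np.where(y == 1, scores, 1.0 - scores)
        p_true = np.clip(p_true, LOG_LOSS_EPS, 1.0 - LOG_LOSS_EPS)
        report.log_loss = float(-np.mean(np.log(p_true)))
        if len(np.unique(y)) == 2:
            _, _, auc = roc_curve(scores, y)
            report.roc_auc = auc
    return report


def roc_curve(scores, y_true) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC over thresholds at distinct scores.

    Returns (fpr, tpr, auc) with the curve anchored at (0,0) and (1,1) and
    monotone non-decreasing in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    tps = np.cumsum(sorted_y == 1)
    fps = np.cumsum(sorted_y == 0)
    # keep only the last sample of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
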