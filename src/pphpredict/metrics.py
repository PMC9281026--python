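"""Binary-classification evaluation: confusion matrix, the six summary
metrics (precision, recall, accuracy, F-score, MCC, error rate), ROC/AUC,
and multi-run aggregation.

The positive class is the outcome of interest (hemorrhage present, the
minority). Ratios with zero denominators are reported as 0 together with
a degeneracy flag rather than raising mid-pipeline. Display rounding is
4 decimal places; stored values keep full precision.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    precision: float
    recall: float
    accuracy: float
    f_score: float
    mcc: float
    error_rate: float
    auc: float | None = None
    confusion: ConfusionMatrix | None = None
    run_id: int | None = None
    degenerate: tuple[str, ...] = ()

    METRICS = ("precision", "recall", "accuracy", "f_score", "mcc", "error_rate")

    def to_dict(self) -> dict:
        d = {m: getattr(self, m) for m in self.METRICS}
        d["auc"] = self.auc
        d["run_id"] = self.run_id
        d["degenerate"] = list(self.degenerate)
        if self.confusion is not None:
            d["confusion"] = dataclasses.asdict(self.confusion)
        return d

    def rounded(self, ndigits: int = 4) -> dict:
        """Display form matching 4-decimal report tables."""
        out = {m: round(getattr(self, m), ndigits) for m in self.METRICS}
        if self.auc is not None:
            out["auc"] = round(self.auc, ndigits)
        return out


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation with class 1 positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("entries must be binary")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix, run_id: int | None = None) -> EvaluationReport:
    """The six summary metrics from a confusion matrix.

    precision = tp/(tp+fp); recall = tp/(tp+fn); accuracy = (tp+tn)/n;
    F = 2PR/(P+R); MCC = (tp·tn − fp·fn)/sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn));
    error = 1 − accuracy.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    degen: list[str] = []
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", degen)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", degen)
    accuracy = (cm.tp + cm.tn) / cm.n
    f_score = _ratio(2 * precision * recall, precision + recall, "f_score", degen)
    denom = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = _ratio(cm.tp * cm.tn - cm.fp * cm.fn, denom, "mcc", degen)
    return EvaluationReport(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f_score=f_score,
        mcc=mcc,
        error_rate=1.0 - accuracy,
        confusion=cm,
        run_id=run_id,
        degenerate=tuple(degen),
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep over unique scores and trapezoidal
    AUC. Equal scores are grouped so ties move diagonally. Returns the
    (FPR, TPR) point array and the area."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("inputs must be equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    # cumulative counts at the end of each tie group
    boundaries = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    group_ends = np.append(boundaries, s.size - 1)
    tps = np.cumsum(y == 1)[group_ends]
    fps = np.cumsum(y == 0)[group_ends]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


def aggregate_runs(reports: list[EvaluationReport]) -> EvaluationReport:
    """Arithmetic mean of each scalar metric across runs; confusion
    matrices are summed when every run carries one."""
    if not reports:
        raise ValueError("empty report list")
    means = {m: float(np.mean([getattr(r, m) for r in reports])) for m in EvaluationReport.METRICS}
    aucs = [r.auc for r in reports if r.auc is not None]
    cms = [r.confusion for r in reports]
    total = None
    if all(c is not None for c in cms):
        total = ConfusionMatrix(
            tp=sum(c.tp for c in cms),
            fp=sum(c.fp for c in cms),
            tn=sum(c.tn for c in cms),
            fn=sum(c.fn for c in cms),
        )
    return EvaluationReport(
        **means,
        auc=float(np.mean(aucs)) if aucs else None,
        confusion=total,
        run_id=None,
        degenerate=tuple(sorted({d for r in reports for d in r.degenerate})),
    )
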