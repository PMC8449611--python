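"""Confusion-matrix construction and metric arithmetic.

Metrics are kept as proportions internally and rendered as
nearest-integer percentages for reporting.  Undefined metrics (zero
denominators) are carried as ``None`` and rendered ``"NA"`` — never
silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus_io import GroundTruth
from .offlabel import OffLabelRecord


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/precision/recall/F1 as proportions; None = undefined."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def as_percentages(self) -> dict[str, object]:
        """Nearest-integer percentages; undefined values render "NA"."""
        return {
            name: ("NA" if value is None else round(100 * value))
            for name, value in (
                ("accuracy", self.accuracy),
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
            )
        }


def confusion_matrix(predicted: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    """Count TP/FP/FN/TN from aligned prediction and truth lists."""
    if len(predicted) != len(truth):
        raise EvaluationError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if not predicted:
        raise EvaluationError("empty input")
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """Derive accuracy, precision, recall and F1 from the four cells.

    accuracy=(tp+tn)/total, precision=tp/(tp+fp), recall=tp/(tp+fn),
    F1 = harmonic mean of precision and recall.  A zero denominator
    yields None for that metric rather than an arithmetic failure.
    """
    if cm.total < 1:
        raise EvaluationError("all-zero confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    f1: Optional[float]
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def evaluate_end_to_end(
    records: Sequence[OffLabelRecord],
    truths: Sequence[GroundTruth],
    exclude_ambiguous: bool = False,
) -> tuple[ConfusionMatrix, MetricsReport, dict[str, int]]:
    """Score per-post off-label predictions against planted truth.

    A post's prediction is positive when any of its records is
    off-label.  Posts with neither an extracted pair nor a planted pair
    carry no drug–indication information and are excluded from scoring;
    posts marked ambiguous are additionally excluded when
    ``exclude_ambiguous`` is set.  Returns the confusion matrix, the
    derived metrics, and a summary with exclusion counts.
    """
    truth_by_id = {t.post_id: t for t in truths}
    predicted_pos: dict[str, bool] = {}
    for r in records:
        if r.post_id not in truth_by_id:
            raise EvaluationError(f"no ground truth for scored post {r.post_id!r}")
        predicted_pos[r.post_id] = predicted_pos.get(r.post_id, False) or r.off_label

    scored_ids = sorted(
        pid
        for pid, t in truth_by_id.items()
        if t.planted_pairs or pid in predicted_pos
    )
    n_ambiguous = sum(1 for pid in scored_ids if truth_by_id[pid].ambiguous)
    if exclude_ambiguous:
        scored_ids = [pid for pid in scored_ids if not truth_by_id[pid].ambiguous]
    n_unpairable = len(truth_by_id) - len(scored_ids) - (n_ambiguous if exclude_ambiguous else 0)

    if not scored_ids:
        raise EvaluationError("no scorable posts")
    predictions = [predicted_pos.get(pid, False) for pid in scored_ids]
    actual = [truth_by_id[pid].off_label_truth for pid in scored_ids]
    cm = confusion_matrix(predictions, actual)
    summary = {
        "n_scored": len(scored_ids),
        "n_excluded_ambiguous": n_ambiguous if exclude_ambiguous else 0,
        "n_excluded_unpairable": n_unpairable,
    }
    return cm, metrics_from_cm(cm), summary
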