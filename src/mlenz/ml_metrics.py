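"""Multi-label evaluation metrics.

Example-based metrics (hamming loss, subset accuracy) score each instance's
predicted label set against the truth and average over instances;
label-based metrics reduce per-class binary confusion counts, either by
averaging per-class rates (macro) or by pooling the counts first (micro).

Conventions: a precision or recall whose denominator is zero (a class never
predicted, or absent from the truth) is defined as 0 and flagged, so that
macro averages are never inflated by vacuous classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mlenz.rank_loss import LabelSet
from mlenz.threshold_calibration import PredictedLabelSet

LabelLike = LabelSet | PredictedLabelSet


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class binary confusion counts over N evaluated instances."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        n = self.tp + self.fp + self.tn + self.fn
        if not (n == n[0]).all():
            raise ValueError("per-class counts must sum to the same N for every class")

    @property
    def q(self) -> int:
        return self.tp.size

    @property
    def n_instances(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


@dataclass(frozen=True)
class MetricsReport:
    """All example-based and label-based quantities for one prediction set."""

    hamming_loss: float
    subset_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    counts: ConfusionCounts
    n_instances: int
    zero_denominator_classes: tuple[int, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            "hamming_loss": self.hamming_loss,
            "subset_accuracy": self.subset_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
        }

    def to_text(self) -> str:
        lines = [f"{k}\t{v:.6f}" for k, v in self.as_dict().items()]
        lines.append(f"n_instances\t{self.n_instances}")
        return "\n".join(lines) + "\n"


def _check_lengths(preds: Sequence[LabelLike], truths: Sequence[LabelLike]) -> int:
    if len(preds) != len(truths):
        raise ValueError(f"{len(preds)} predictions but {len(truths)} truths")
    if len(preds) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    return len(preds)


def confusion_counts(
    preds: Sequence[LabelLike], truths: Sequence[LabelLike], q: int
) -> ConfusionCounts:
    """Per-class TP/FP/TN/FN over aligned prediction and truth lists."""
    n = _check_lengths(preds, truths)
    tp = np.zeros(q, dtype=int)
    fp = np.zeros(q, dtype=int)
    tn = np.zeros(q, dtype=int)
    fn = np.zeros(q, dtype=int)
    for pred, true in zip(preds, truths):
        for j in range(1, q + 1):
            in_pred, in_true = j in pred, j in true
            if in_pred and in_true:
                tp[j - 1] += 1
            elif in_pred:
                fp[j - 1] += 1
            elif in_true:
                fn[j - 1] += 1
            else:
                tn[j - 1] += 1
    assert (tp + fp + tn + fn == n).all()
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall and F1 for one class's binary counts."""
    total = tp + fp + tn + fn
    accuracy, _ = _safe_div(tp + tn, total)
    precision, _ = _safe_div(tp, tp + fp)
    recall, _ = _safe_div(tp, tp + fn)
    f1, _ = _safe_div(2 * precision * recall, precision + recall)
    return accuracy, precision, recall, f1


def hamming_loss(
    preds: Sequence[LabelLike], truths: Sequence[LabelLike], q: int
) -> float:
    """Mean fraction of instance-label pairs predicted incorrectly:
    (1/N) sum_i |pred_i Δ true_i| / Q."""
    n = _check_lengths(preds, truths)
    total = 0
    for pred, true in zip(preds, truths):
        p = frozenset(pred.members if hasattr(pred, "members") else pred)
        t = frozenset(true.members if hasattr(true, "members") else true)
        total += len(p ^ t)
    return total / (n * q)


def subset_accuracy(preds: Sequence[LabelLike], truths: Sequence[LabelLike]) -> float:
    """Fraction of instances whose predicted set equals the truth exactly."""
    n = _check_lengths(preds, truths)
    exact = sum(
        1
        for pred, true in zip(preds, truths)
        if frozenset(pred.members) == frozenset(true.members)
    )
    return exact / n


def macro_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Unweighted per-class means of precision and recall; macro-F1 is the
    mean of the per-class harmonic means (not the harmonic mean of the
    macro averages)."""
    precisions, recalls, f1s = [], [], []
    for j in range(counts.q):
        p, _ = _safe_div(counts.tp[j], counts.tp[j] + counts.fp[j])
        r, _ = _safe_div(counts.tp[j], counts.tp[j] + counts.fn[j])
        f, _ = _safe_div(2 * p * r, p + r)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return float(np.mean(precisions)), float(np.mean(recalls)), float(np.mean(f1s))


def micro_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Metrics on pooled counts: precision = ΣTP/(ΣTP+ΣFP), recall =
    ΣTP/(ΣTP+ΣFN), F1 their harmonic mean."""
    tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
    precision, _ = _safe_div(tp, tp + fp)
    recall, _ = _safe_div(tp, tp + fn)
    f1, _ = _safe_div(2 * precision * recall, precision + recall)
    return float(precision), float(recall), float(f1)


def evaluate_predictions(
    preds: Sequence[LabelLike], truths: Sequence[LabelLike], q: int
) -> MetricsReport:
    """Compute the full metrics report for aligned predictions and truths."""
    counts = confusion_counts(preds, truths, q)
    zero_flagged = []
    for j in range(counts.q):
        _, pf = _safe_div(counts.tp[j], counts.tp[j] + counts.fp[j])
        _, rf = _safe_div(counts.tp[j], counts.tp[j] + counts.fn[j])
        if pf or rf:
            zero_flagged.append(j + 1)
    ma_p, ma_r, ma_f = macro_metrics(counts)
    mi_p, mi_r, mi_f = micro_metrics(counts)
    return MetricsReport(
        hamming_loss=hamming_loss(preds, truths, q),
        subset_accuracy=subset_accuracy(preds, truths),
        macro_precision=ma_p,
        macro_recall=ma_r,
        macro_f1=ma_f,
        micro_precision=mi_p,
        micro_recall=mi_r,
        micro_f1=mi_f,
        counts=counts,
        n_instances=counts.n_instances,
        zero_denominator_classes=tuple(zero_flagged),
    )


def write_metrics_tsv(
    reports: Sequence[MetricsReport], path: str | Path, run_ids: Sequence[str] | None = None
) -> None:
    """Write one row per report as a machine-readable TSV table."""
    keys = list(reports[0].as_dict())
    header = "run\t" + "\t".join(keys) + "\tn_instances\n"
    rows = []
    for i, rep in enumerate(reports):
        rid = run_ids[i] if run_ids is not None else str(i)
        vals = rep.as_dict()
        rows.append(
            rid + "\t" + "\t".join(f"{vals[k]:.6f}" for k in keys) + f"\t{rep.n_instances}\n"
        )
    Path(path).write_text(header + "".join(rows))
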