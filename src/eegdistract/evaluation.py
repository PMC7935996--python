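"""Classification metrics and multi-subject aggregation.

Distraction (class 2) is the positive class throughout: a false negative
is a distracted epoch mistaken for attentive, the clinically expensive
error, so recall for distraction is the headline secondary metric next to
accuracy.  Subject summaries report per-subject mean +/- sample standard
deviation of the outer-fold accuracies and a grand mean across subjects,
formatted to 0.1 percentage point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "precision_recall_f1",
    "SubjectSummary",
    "summarize_subjects",
]

POSITIVE = 1  # distracted


@dataclass
class ConfusionMatrix:
    """Counts with positive = distracted."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def confusion(predictions, labels) -> ConfusionMatrix:
    """Count tp/fp/fn/tn with distracted (class index 1) as positive."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum((pred == POSITIVE) & (lab == POSITIVE))),
        fp=int(np.sum((pred == POSITIVE) & (lab != POSITIVE))),
        fn=int(np.sum((pred != POSITIVE) & (lab == POSITIVE))),
        tn=int(np.sum((pred != POSITIVE) & (lab != POSITIVE))),
    )


def precision_recall_f1(cm: ConfusionMatrix):
    """Precision, recall and F1 for the distraction class.

    Undefined denominators yield NaN with a warning, never a silent 0.
    """
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        warnings.warn("precision undefined: no positive predictions")
        precision = math.nan
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        warnings.warn("recall undefined: no positive labels")
        recall = math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass
class SubjectSummary:
    """Per-subject and grand accuracy statistics (percent)."""

    subjects: list           # subject ids, in input order
    means_pct: np.ndarray    # per-subject mean accuracy, %
    stds_pct: np.ndarray     # per-subject sample std over folds, %
    grand_mean_pct: float
    grand_std_pct: float

    def render(self) -> str:
        lines = ["subject\taccuracy"]
        for s, m, sd in zip(self.subjects, self.means_pct, self.stds_pct):
            lines.append(f"{s}\t{m:.1f} ± {sd:.1f}")
        lines.append(
            f"mean\t{self.grand_mean_pct:.1f} ± {self.grand_std_pct:.1f}"
        )
        return "\n".join(lines)

    @classmethod
    def parse(cls, text: str) -> "SubjectSummary":
        subjects, means, stds = [], [], []
        grand = None
        for line in text.strip().splitlines()[1:]:
            name, val = line.split("\t")
            m, sd = (float(v) for v in val.split(" ± "))
            if name == "mean":
                grand = (m, sd)
            else:
                subjects.append(name)
                means.append(m)
                stds.append(sd)
        return cls(subjects, np.array(means), np.array(stds), *grand)


def summarize_subjects(reports) -> SubjectSummary:
    """Aggregate per-subject nested-CV reports in percent.

    Per subject: mean +/- sample std of the outer-fold accuracies; grand
    mean and sample std across the per-subject means.  Values are rounded
    to 0.1 percentage point so the rendered table round-trips exactly.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("at least one report required")
    subjects = [r.subject_id for r in reports]
    means = np.array([round(100 * r.mean_accuracy, 1) for r in reports])
    stds = np.array([round(100 * r.std_accuracy, 1) for r in reports])
    grand_mean = round(float(means.mean()), 1)
    grand_std = round(float(means.std(ddof=1)), 1) if len(means) > 1 else 0.0
    return SubjectSummary(
        subjects=subjects,
        means_pct=means,
        stds_pct=stds,
        grand_mean_pct=grand_mean,
        grand_std_pct=grand_std,
    )


def pooled_metrics(reports):
    """Epoch-level pooled precision/recall/F1 over a list of reports."""
    pred = np.concatenate([r.predictions for r in reports])
    lab = np.concatenate([r.labels for r in reports])
    return precision_recall_f1(confusion(pred, lab))


def subject_averaged_metrics(reports):
    """Subject-averaged precision/recall/F1 (the default aggregation)."""
    triples = [
        precision_recall_f1(confusion(r.predictions, r.labels))
        for r in reports
    ]
    arr = np.array(triples, dtype=float)
    return tuple(np.nanmean(arr, axis=0))
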