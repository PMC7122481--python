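"""Confusion counts, sensitivity/specificity/accuracy, ROC and AUC.

HCC is the positive class throughout:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

A metric whose denominator is zero (e.g. specificity with no negative
truth samples) is reported as absent (None), never as 0. AUC follows the
Mann-Whitney convention: the probability that a random positive outscores
a random negative, with tied scores credited 0.5 — equivalent to the
trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .io import SampleLabels


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg_truth(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        """Pool counts across datasets (micro-averaging)."""
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )

    @classmethod
    def from_correct_totals(
        cls, correct_pos: int = 0, total_pos: int = 0,
        correct_neg: int = 0, total_neg: int = 0,
    ) -> "ConfusionCounts":
        """Build counts from per-class correct/total tallies.

        Convenient for pooling published per-dataset results reported as
        "correct/total" fractions.
        """
        if correct_pos > total_pos or correct_neg > total_neg:
            raise ValueError("correct count exceeds total")
        return cls(
            tp=correct_pos,
            fn=total_pos - correct_pos,
            tn=correct_neg,
            fp=total_neg - correct_neg,
        )


@dataclass
class MetricsReport:
    """Sensitivity/specificity/accuracy (fractions) with optional AUC.

    Undefined metrics are None. ``as_percent`` renders rounded percentages
    (half-up) for human-facing reports; the raw fractions stay exact here.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    auc: float | None = None

    def as_percent(self, decimals: int = 2) -> dict[str, float | None]:
        from decimal import Decimal, ROUND_HALF_UP

        def pct(x: float | None) -> float | None:
            if x is None:
                return None
            q = Decimal(1).scaleb(-decimals)
            return float(Decimal(str(x * 100)).quantize(q, rounding=ROUND_HALF_UP))

        return {
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "accuracy": pct(self.accuracy),
        }

    def to_dict(self) -> dict:
        return {
            "counts": asdict(self.counts),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def confusion(pred: SampleLabels, truth: SampleLabels) -> ConfusionCounts:
    """Exact confusion counts over aligned samples (positive = HCC)."""
    if set(pred.sample_ids) != set(truth.sample_ids):
        only_p = sorted(set(pred.sample_ids) - set(truth.sample_ids))[:5]
        only_t = sorted(set(truth.sample_ids) - set(pred.sample_ids))[:5]
        raise ValueError(
            f"sample id mismatch between predictions and truth "
            f"(pred-only {only_p}, truth-only {only_t})"
        )
    t = truth.subset(pred.sample_ids)
    p = pred.labels
    y = t.labels
    return ConfusionCounts(
        tp=int((p & y).sum()),
        fn=int((~p & y).sum()),
        tn=int((~p & ~y).sum()),
        fp=int((p & ~y).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Exact rational evaluation of sensitivity/specificity/accuracy."""
    sens = c.tp / c.n_pos_truth if c.n_pos_truth else None
    spec = c.tn / c.n_neg_truth if c.n_neg_truth else None
    acc = (c.tp + c.tn) / c.total if c.total else None
    return MetricsReport(counts=c, sensitivity=sens, specificity=spec, accuracy=acc)


def micro_average(counts: "list[ConfusionCounts]") -> MetricsReport:
    """Pool confusion counts across datasets, then compute metrics.

    Micro-averaging: metrics of the summed counts, not means of
    per-dataset metrics.
    """
    if not counts:
        raise ValueError("need at least one ConfusionCounts to pool")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return compute_metrics(total)


def roc_auc(scores: np.ndarray, truth: SampleLabels) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold, fpr, tpr) and Mann-Whitney AUC.

    Thresholds sweep every distinct score (ties grouped). Requires both
    classes present and finite scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = truth.labels.astype(int)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and truth length mismatch")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, scores)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    auc = float(roc_auc_score(y, scores))
    return points, auc
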