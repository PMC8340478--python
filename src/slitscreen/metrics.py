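"""Screening evaluation: confusion counts, derived rates, ROC/AUC, and the
stratified 7:2:1 dataset split.

Conventions: the positive class is cataract throughout (sensitivity is the
cataract-detection rate).  Rates with a zero denominator are reported as
``None`` (explicitly undefined), never silently 0.  The stratified split
uses largest-remainder rounding per class so integer class counts partition
exactly (720 + 800 items at 7:2:1 give 504/144/72 and 560/160/80).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "rates",
    "roc_auc",
    "split_dataset",
    "write_report_csv",
    "write_report_json",
    "write_roc_csv",
]

POSITIVE = "cataract"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Derived rates (None where the denominator is zero) plus ROC fields."""

    acc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    auc: float | None = None


def confusion_counts(
    predicted: Sequence[str],
    true: Sequence[str],
    positive_class: str = POSITIVE,
) -> ConfusionCounts:
    """Exact four-cell tally of predictions against truth."""
    if len(predicted) != len(true):
        raise ValueError("predicted and true labels must have equal length")
    if len(true) == 0:
        raise ValueError("need at least one label pair")
    pred = np.asarray(predicted) == positive_class
    gold = np.asarray(true) == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pred & gold)),
        fp=int(np.sum(pred & ~gold)),
        tn=int(np.sum(~pred & ~gold)),
        fn=int(np.sum(~pred & gold)),
    )


def f1_score(precision: float, sensitivity: float) -> float | None:
    """Harmonic mean 2 P R / (P + R); None when both rates are zero."""
    if precision + sensitivity == 0:
        return None
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def rates(c: ConfusionCounts) -> EvalReport:
    """Accuracy, specificity, precision, sensitivity and F1 from the counts."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    acc = (c.tp + c.tn) / c.total
    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.fp + c.tn)
    prec = ratio(c.tp, c.tp + c.fp)
    f1 = f1_score(prec, sens) if prec is not None and sens is not None else None
    return EvalReport(
        acc=acc, sensitivity=sens, specificity=spec, precision=prec, f1=f1
    )


def roc_auc(
    scores: Sequence[float],
    true: Sequence[str],
    positive_class: str = POSITIVE,
) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep over the scores and trapezoidal AUC.

    Tied scores share a threshold, which makes the trapezoidal area equal to
    the pairwise rank statistic with half-credit for ties.  Requires at least
    one positive and one negative item.
    """
    y = (np.asarray(true) == positive_class).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("scores and labels must have equal length")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one positive and one negative item")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    ratios = np.asarray(ratios, dtype=float)
    quotas = n * ratios / ratios.sum()
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def split_dataset(
    labels: Sequence[str],
    ratios: Sequence[float] = (7, 2, 1),
    seed: int = 0,
) -> tuple[list[int], list[int], list[int]]:
    """Stratified train/validation/test split of item indices.

    Each class is partitioned by the ratios with largest-remainder rounding,
    after a seeded shuffle within the class; the three index lists are
    disjoint and together exhaust the input.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    splits: tuple[list[int], list[int], list[int]] = ([], [], [])
    for cls in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == cls]
        if not idx:
            raise ValueError(f"empty class {cls!r}")
        idx = list(rng.permutation(idx))
        counts = _largest_remainder(len(idx), ratios)
        start = 0
        for part, count in zip(splits, counts):
            part.extend(int(i) for i in idx[start : start + count])
            start += count
    return splits


# -- report writers ----------------------------------------------------------

_COLUMNS = ["Acc", "Sensitivity", "Specificity", "Pre", "F1"]


def _row(report: EvalReport) -> list[str]:
    vals = [report.acc, report.sensitivity, report.specificity,
            report.precision, report.f1]
    return ["undefined" if v is None else f"{v:.4f}" for v in vals]


def write_report_csv(path, reports: dict[str, EvalReport]) -> None:
    """One row per method, Table-style column order, rates at 4 d.p."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Method"] + _COLUMNS)
        for method, report in reports.items():
            writer.writerow([method] + _row(report))


def write_report_json(path, reports: dict[str, EvalReport]) -> None:
    payload = {
        method: {
            "acc": r.acc, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "precision": r.precision,
            "f1": r.f1, "auc": r.auc,
        }
        for method, r in reports.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_roc_csv(path, roc_points: Sequence[tuple[float, float]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr"])
        writer.writerows(roc_points)
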