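"""Splits, imbalanced binary-classification metrics, and comparison tables.

The positive class is "crisis" (label 1) throughout: precision, recall
and F1 all refer to it.  Zero-denominator metrics are defined as 0 (not
NaN) so degenerate predictors — e.g. the all-negative majority-class
floor — remain comparable in the same tables.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "stratified_split",
    "confusion_and_metrics",
    "relative_improvement",
    "majority_class_accuracy",
    "metrics_table",
    "parse_metrics_table",
]

_COLUMNS = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the four headline metrics for the crisis class."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        if min(tp, fp, fn, tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        total = tp + fp + fn + tn
        acc = (tp + tn) / total if total else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        object.__setattr__(self, "accuracy", acc)
        object.__setattr__(self, "precision", prec)
        object.__setattr__(self, "recall", rec)
        object.__setattr__(self, "f1", f1)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def confusion_and_metrics(predicted, truth) -> MetricsReport:
    """Confusion counts and metrics for 0/1 predictions against 0/1 truth."""
    predicted = np.asarray(predicted, dtype=int).ravel()
    truth = np.asarray(truth, dtype=int).ravel()
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape[0]} predictions, {truth.shape[0]} labels"
        )
    for arr, what in ((predicted, "predictions"), (truth, "labels")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{what} must be binary 0/1")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(labels, test_fraction: float, seed: int):
    """Class-stratified random train/test split, reproducible by seed.

    Each class contributes ``round_half_up(test_fraction * class_size)``
    members to the test set; e.g. a 265-positive / 1000-negative cohort at
    ``test_fraction=0.2`` always yields 53 positive and 200 negative test
    samples.  Returns sorted ``(train_indices, test_indices)`` that are
    disjoint and exhaustive.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels).ravel()
    rng = np.random.default_rng(seed)
    test_parts = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = _round_half_up(test_fraction * idx.size)
        test_parts.append(rng.permutation(idx)[:n_test])
    test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], dtype=int)
    mask = np.ones(labels.size, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


def relative_improvement(new_value: float, reference_value: float) -> float:
    """Percent improvement ``100 * (new - ref) / ref``, rounded to 2 decimals."""
    if reference_value <= 0:
        raise ValueError("reference_value must be positive")
    return round(100.0 * (new_value - reference_value) / reference_value, 2)


def majority_class_accuracy(labels) -> float:
    """Accuracy of always predicting the most frequent class (the floor)."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    return counts.max() / labels.size


def metrics_table(reports: dict, fmt: str = "text") -> str:
    """Render method -> MetricsReport as a comparison table.

    Rows follow the insertion order of ``reports``; values print with 4
    decimals.  ``fmt="text"`` gives an aligned human-readable table,
    ``fmt="tsv"`` a tab-separated one that :func:`parse_metrics_table`
    reads back exactly.
    """
    if not reports:
        raise ValueError("at least one report required")
    header = ("Method",) + tuple(c.capitalize() for c in _COLUMNS)
    rows = [
        (name,) + tuple(f"{getattr(rep, c):.4f}" for c in _COLUMNS)
        for name, rep in reports.items()
    ]
    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown table format {fmt!r}")
    widths = [max(len(str(r[c])) for r in [header] + rows) for c in range(len(header))]
    lines = []
    for r in [header] + rows:
        lines.append("  ".join(str(v).ljust(w) for v, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"


def parse_metrics_table(text: str) -> dict:
    """Parse a TSV table from :func:`metrics_table` back to metric dicts."""
    lines = [ln for ln in io.StringIO(text).read().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out: dict[str, dict[str, float]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        out[parts[0]] = {
            h.lower(): float(v) for h, v in zip(header[1:], parts[1:])
        }
    return out
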