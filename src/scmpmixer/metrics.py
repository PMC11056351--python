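"""Confusion-matrix based evaluation.

Per-class metrics follow the one-vs-rest convention: for class i the
confusion matrix collapses to TP/FP/FN/TN and

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Pr  = TP / (TP + FP)
    Re  = TP / (TP + FN)
    F1  = 2 * Pr * Re / (Pr + Re)

all reported as percentages. The macro summary is the unweighted
arithmetic mean over classes, computed on unrounded per-class values;
rounding (half-up, two decimals) happens only at report time. Note the
one-vs-rest "Acc" counts true negatives, so with more than two classes its
macro mean exceeds pooled multi-class accuracy whenever any sample is
misclassified.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray
    class_names: list

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


@dataclass
class ClassCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricRow:
    """Percentages in [0, 100]; held unrounded, rounded only for display."""

    acc: float
    pr: float
    re: float
    f1: float

    def rounded(self) -> "MetricRow":
        return MetricRow(*(round_half_up(v) for v in
                           (self.acc, self.pr, self.re, self.f1)))

    def as_dict(self, rounded: bool = True) -> dict:
        row = self.rounded() if rounded else self
        return {"acc": row.acc, "pr": row.pr, "re": row.re, "f1": row.f1}


def round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_matrix(true_labels, predicted_labels, num_classes: int,
                     class_names=None) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        bad = (arr < 0) | (arr >= num_classes)
        if bad.any():
            raise ValueError(
                f"{name} label {arr[bad][0]} outside [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    if class_names is None:
        class_names = [str(i) for i in range(num_classes)]
    return ConfusionMatrix(counts, list(class_names))


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> ClassCounts:
    c = cm.counts
    if not 0 <= class_index < cm.num_classes:
        raise IndexError(f"class index {class_index} out of range")
    tp = int(c[class_index, class_index])
    fn = int(c[class_index].sum()) - tp
    fp = int(c[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ClassCounts(tp, fp, fn, tn)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def class_metrics(counts: ClassCounts) -> MetricRow:
    if counts.total <= 0:
        raise ValueError("empty confusion matrix")
    acc = (counts.tp + counts.tn) / counts.total * 100.0
    pr = _safe_ratio(counts.tp, counts.tp + counts.fp, "precision") * 100.0
    re = _safe_ratio(counts.tp, counts.tp + counts.fn, "recall") * 100.0
    f1 = 0.0 if pr + re == 0 else 2.0 * pr * re / (pr + re)
    return MetricRow(acc, pr, re, f1)


def macro_summary(rows) -> MetricRow:
    rows = list(rows)
    if not rows:
        raise ValueError("macro summary of an empty row list")
    return MetricRow(
        acc=float(np.mean([r.acc for r in rows])),
        pr=float(np.mean([r.pr for r in rows])),
        re=float(np.mean([r.re for r in rows])),
        f1=float(np.mean([r.f1 for r in rows])),
    )


def pooled_accuracy(cm: ConfusionMatrix) -> float:
    """Plain multi-class accuracy (trace / total), in percent."""
    return float(np.trace(cm.counts)) / cm.total * 100.0


def report(cm: ConfusionMatrix, class_names=None, out_dir=None) -> pd.DataFrame:
    """Per-class table plus a final MACRO row (rounded to 2 decimals).

    When ``out_dir`` is given, writes metrics.csv, metrics.json and
    confusion_matrix.csv there.
    """
    names = list(class_names) if class_names is not None else cm.class_names
    rows = [class_metrics(one_vs_rest_counts(cm, i))
            for i in range(cm.num_classes)]
    macro = macro_summary(rows)
    records = [{"class": n, **r.as_dict()} for n, r in zip(names, rows)]
    records.append({"class": "MACRO", **macro.as_dict()})
    frame = pd.DataFrame.from_records(records,
                                      columns=["class", "acc", "pr", "re", "f1"])
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            frame.to_csv(out / "metrics.csv", index=False)
            (out / "metrics.json").write_text(
                json.dumps(frame.to_dict(orient="records"), indent=2))
            cm.to_frame().to_csv(out / "confusion_matrix.csv")
        except OSError as exc:
            raise OSError(f"failed writing report under {out}: {exc}") from exc
        logger.info("wrote metrics report to %s", out)
    return frame
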