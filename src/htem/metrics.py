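"""Confusion-matrix metrics: macro P/R/F1, accuracy, interpolated AP, mAP.

Per-class precision, recall and F1 are derived from one-vs-rest counts of a
K x K confusion matrix and macro-averaged (unweighted over classes).  On a
class-balanced evaluation set macro recall equals accuracy, which is the
signature the headline tables of this protocol show.

Average precision is the interpolated kind: with positives ranked at
positions r_1 < ... < r_M after sorting scores descending (ties keep the
original order), AP = (1/M) * sum_i max_{r >= r_i} precision(r).  mAP is
the arithmetic mean of APs over datasets or classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix", "BinaryCounts", "RankedScores", "EvalReport",
    "confusion_matrix", "binary_counts", "prf_accuracy",
    "average_precision", "mean_ap",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (K true, K predicted)
    class_names: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self) -> str:
        names = self.class_names or [str(i) for i in range(self.num_classes)]
        lines = ["true\\pred," + ",".join(names)]
        for i, row in enumerate(self.counts):
            lines.append(names[i] + "," + ",".join(map(str, row)))
        return "\n".join(lines)

    def plot(self, path) -> None:
        """Render a heat map to ``path`` (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.counts, cmap="viridis")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class BinaryCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("binary counts must be non-negative")


@dataclass
class RankedScores:
    scores: np.ndarray
    labels: np.ndarray                       # 1 = positive

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")


def confusion_matrix(true_labels, predicted_labels, num_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if t.size and ((t < 0).any() or (t >= num_classes).any()
                   or (p < 0).any() or (p >= num_classes).any()):
        raise ValueError(f"labels out of range [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names)


def binary_counts(cm: ConfusionMatrix, positive_class: int) -> BinaryCounts:
    if positive_class >= cm.num_classes:
        raise ValueError(f"positive class {positive_class} out of range")
    c = cm.counts
    tp = int(c[positive_class, positive_class])
    fn = int(c[positive_class].sum()) - tp
    fp = int(c[:, positive_class].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, what: str, cls: int) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls} (zero denominator); "
                      "contributing 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def prf_accuracy(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(macro recall, macro precision, macro F1, accuracy) of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    ps, rs, f1s = [], [], []
    for k in range(cm.num_classes):
        b = binary_counts(cm, k)
        p = _safe_div(b.tp, b.tp + b.fp, "precision", k)
        r = _safe_div(b.tp, b.tp + b.fn, "recall", k)
        f1 = _safe_div(2 * p * r, p + r, "F1", k)
        ps.append(p)
        rs.append(r)
        f1s.append(f1)
    accuracy = np.trace(cm.counts) / cm.total
    return float(np.mean(rs)), float(np.mean(ps)), float(np.mean(f1s)), float(accuracy)


def average_precision(rs: RankedScores) -> float:
    """Interpolated average precision of a ranked binary scoring."""
    m = int(rs.labels.sum())
    if m == 0:
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-rs.scores, kind="stable")    # ties keep original order
    labels = rs.labels[order]
    ranks = np.arange(1, labels.size + 1)
    precision = np.cumsum(labels) / ranks
    # interpolated precision: running max from the tail
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    return float(p_interp[labels == 1].mean())


def mean_ap(aps) -> float:
    aps = list(aps)
    if not aps:
        raise ValueError("mean AP of an empty list")
    return float(np.mean(aps))


@dataclass
class EvalReport:
    """Confusion matrix plus derived macro metrics (and optional AP/mAP)."""

    cm: ConfusionMatrix
    recall: float = field(init=False)
    precision: float = field(init=False)
    f1: float = field(init=False)
    accuracy: float = field(init=False)
    aps: list[float] | None = None

    def __post_init__(self):
        self.recall, self.precision, self.f1, self.accuracy = prf_accuracy(self.cm)

    @property
    def map(self) -> float | None:
        return mean_ap(self.aps) if self.aps else None

    def per_class(self) -> list[dict]:
        rows = []
        names = self.cm.class_names or [str(i) for i in range(self.cm.num_classes)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for k in range(self.cm.num_classes):
                b = binary_counts(self.cm, k)
                p = b.tp / (b.tp + b.fp) if b.tp + b.fp else 0.0
                r = b.tp / (b.tp + b.fn) if b.tp + b.fn else 0.0
                f1 = 2 * p * r / (p + r) if p + r else 0.0
                rows.append({"class": names[k], "tp": b.tp, "fp": b.fp,
                             "tn": b.tn, "fn": b.fn,
                             "precision": p, "recall": r, "f1": f1})
        return rows

    def to_json(self) -> str:
        return json.dumps({
            "recall": self.recall, "precision": self.precision,
            "f1": self.f1, "accuracy": self.accuracy,
            "mAP": self.map, "aps": self.aps,
            "per_class": self.per_class(),
            "confusion": self.cm.counts.tolist(),
        }, indent=2)

    def to_csv(self) -> str:
        lines = ["class,tp,fp,tn,fn,precision,recall,f1"]
        for row in self.per_class():
            lines.append(",".join(str(row[k]) for k in
                                  ("class", "tp", "fp", "tn", "fn",
                                   "precision", "recall", "f1")))
        lines.append(f"MACRO,,,,,{self.precision},{self.recall},{self.f1}")
        lines.append(f"ACCURACY,,,,,,,{self.accuracy}")
        return "\n".join(lines)
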