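"""Scoring and the axis-correlation analysis.

The headline score is the class-support-weighted F1

    F = Σ_i w_i · 2 P_i R_i / (P_i + R_i),   w_i = support_i / total,

with P_i the column precision and R_i the row recall of a confusion matrix
whose rows are true classes.  A class with P_i + R_i = 0 contributes 0, and
a uniform-weights switch is provided.  The NULL class is included by default;
``exclude_labels`` drops it (both conventions are found in the activity
recognition literature).

The axis-correlation report quantifies the premise behind per-axis action
pictures: same-axis channel pairs across positions should correlate strongly
while cross-axis pairs within a position should not, with |Pearson r| < 0.3
counted as weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import AXES, MultiPositionRecording
from .errors import AnalysisError, ParameterError

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "weighted_f1",
    "accuracy",
    "per_class_metrics",
    "format_report",
    "axis_correlation_report",
    "CorrelationReport",
    "WEAK_CORRELATION_THRESHOLD",
]

WEAK_CORRELATION_THRESHOLD = 0.3


@dataclass(frozen=True)
class ConfusionMatrix:
    """C × C counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.labels)
        if counts.shape != (c, c):
            raise ParameterError(
                f"counts must be ({c}, {c}) for {c} labels; got {counts.shape}"
            )
        if (counts < 0).any():
            raise ParameterError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def drop(self, labels: Sequence[str]) -> "ConfusionMatrix":
        keep = [i for i, lab in enumerate(self.labels) if lab not in set(labels)]
        return ConfusionMatrix(
            self.counts[np.ix_(keep, keep)], tuple(self.labels[i] for i in keep)
        )


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix.  ``labels`` fixes the class order; when
    omitted it is the sorted union of observed labels."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if len(y_true) != len(y_pred):
        raise ParameterError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = tuple(str(v) for v in labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise ParameterError(f"label {unknown!r} not in the class set")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def per_class_metrics(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (precision, recall, F1); 0/0 ratios are defined as 0."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    precision = np.divide(tp, col, out=np.zeros_like(tp), where=col > 0)
    recall = np.divide(tp, row, out=np.zeros_like(tp), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(tp), where=pr > 0)
    return precision, recall, f1


def weighted_f1(
    cm: ConfusionMatrix,
    weights: str = "support",
    exclude_labels: Sequence[str] = (),
) -> float:
    """Weighted mean of per-class F1 scores; in [0, 1], and 1 exactly when
    the matrix is diagonal with every class present."""
    if exclude_labels:
        cm = cm.drop(exclude_labels)
    if cm.total == 0:
        raise ParameterError("confusion matrix is empty")
    _, _, f1 = per_class_metrics(cm)
    if weights == "support":
        w = cm.supports() / cm.total
    elif weights == "uniform":
        w = np.full(len(cm.labels), 1.0 / len(cm.labels))
    else:
        raise ParameterError("weights must be 'support' or 'uniform'")
    return float(np.sum(w * f1))


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ParameterError("confusion matrix is empty")
    return float(np.trace(cm.counts) / cm.total)


def format_report(cm: ConfusionMatrix) -> str:
    """Human-readable per-class table plus the summary scores."""
    precision, recall, f1 = per_class_metrics(cm)
    supports = cm.supports()
    width = max(8, max(len(lab) for lab in cm.labels) + 1)
    lines = [
        f"{'class':<{width}} {'support':>8} {'precision':>10} {'recall':>8} {'f1':>8}"
    ]
    for i, lab in enumerate(cm.labels):
        lines.append(
            f"{lab:<{width}} {supports[i]:>8d} {precision[i]:>10.4f} "
            f"{recall[i]:>8.4f} {f1[i]:>8.4f}"
        )
    lines.append("")
    lines.append(f"weighted F1: {weighted_f1(cm):.4f}")
    lines.append(f"accuracy:    {accuracy(cm):.4f}")
    lines.append("")
    lines.append("confusion matrix (rows = true):")
    head = " " * width + "".join(f"{lab:>{width}}" for lab in cm.labels)
    lines.append(head)
    for i, lab in enumerate(cm.labels):
        lines.append(
            f"{lab:<{width}}"
            + "".join(f"{cm.counts[i, j]:>{width}d}" for j in range(len(cm.labels)))
        )
    return "\n".join(lines)


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise |Pearson r| grouped by relation between the channels.

    ``same_axis`` holds (axis, position A, position B, |r|) for same-axis
    cross-position pairs; ``cross_axis`` holds (position, axis A, axis B, |r|)
    for cross-axis within-position pairs.
    """

    same_axis: tuple[tuple[str, str, str, float], ...]
    cross_axis: tuple[tuple[str, str, str, float], ...]
    excluded_channels: tuple[str, ...]

    @staticmethod
    def _mean(rows) -> float:
        return float(np.mean([r[-1] for r in rows])) if rows else float("nan")

    @staticmethod
    def _weak_fraction(rows) -> float:
        if not rows:
            return float("nan")
        vals = np.array([r[-1] for r in rows])
        return float(np.mean(vals < WEAK_CORRELATION_THRESHOLD))

    @property
    def same_axis_mean(self) -> float:
        return self._mean(self.same_axis)

    @property
    def cross_axis_mean(self) -> float:
        return self._mean(self.cross_axis)

    @property
    def same_axis_weak_fraction(self) -> float:
        return self._weak_fraction(self.same_axis)

    @property
    def cross_axis_weak_fraction(self) -> float:
        return self._weak_fraction(self.cross_axis)


def axis_correlation_report(rec: MultiPositionRecording) -> CorrelationReport:
    """Compare same-axis cross-position against cross-axis within-position
    channel correlations over a recording.

    Constant channels (zero variance) have no defined correlation and are
    excluded with a warning; an all-constant recording is an error.
    """
    if rec.n_samples < 3:
        raise ParameterError("need at least 3 samples per channel")
    P = rec.n_positions
    tri = rec.triaxial  # (P, 3, n)
    sd = tri.std(axis=2)
    constant = sd == 0
    excluded = tuple(
        f"{rec.layout.positions[p]}_{AXES[a]}"
        for p in range(P)
        for a in range(3)
        if constant[p, a]
    )
    if len(excluded) == 3 * P:
        raise AnalysisError("all channels are constant; correlations undefined")
    if excluded:
        warnings.warn(
            f"excluding constant channels from correlation analysis: {excluded}",
            stacklevel=2,
        )
    flat = tri.reshape(3 * P, -1)  # row index p*3 + a
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(flat))
    same_axis = []
    for a in range(3):
        for p in range(P):
            for q in range(p + 1, P):
                if constant[p, a] or constant[q, a]:
                    continue
                same_axis.append(
                    (
                        AXES[a],
                        rec.layout.positions[p],
                        rec.layout.positions[q],
                        float(corr[p * 3 + a, q * 3 + a]),
                    )
                )
    cross_axis = []
    for p in range(P):
        for a in range(3):
            for b in range(a + 1, 3):
                if constant[p, a] or constant[p, b]:
                    continue
                cross_axis.append(
                    (
                        rec.layout.positions[p],
                        AXES[a],
                        AXES[b],
                        float(corr[p * 3 + a, p * 3 + b]),
                    )
                )
    return CorrelationReport(tuple(same_axis), tuple(cross_axis), excluded)
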