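"""Imbalance-aware evaluation: confusion matrix, one-vs-rest metrics,
precision-recall curves.

For each class ``c`` the confusion matrix is reduced one-vs-rest to
TP/FP/TN/FN, from which

    RE (recall)      = TP / (TP + FN)
    PR (precision)   = TP / (TP + FP)
    SP (specificity) = TN / (TN + FP)
    F1               = 2·RE·PR / (RE + PR)

Summary numbers are support-weighted means of the per-class values (macro
means are also reported).  Support weighting makes the aggregate recall
algebraically identical to overall accuracy — the pattern visible when
ACC and RE coincide in headline tables — because
``Σ_c (n_c/n)·(TP_c/n_c) = Σ_c TP_c / n = trace/total``.

For ranking quality on minority classes, :func:`pr_curve` computes the
one-vs-rest precision-recall curve and its area as step-wise average
precision ``Σ (R_k − R_{k−1})·P_k`` (no trapezoidal interpolation, which
is optimistic on PR curves).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import CLASS_NAMES

__all__ = [
    "ClassCounts",
    "EvaluationReport",
    "PRCurve",
    "confusion_matrix",
    "one_vs_rest_counts",
    "report",
    "pr_curve",
    "pr_curves_from_probs",
    "write_report_csv",
    "write_confusion_text",
    "write_pr_curve_csv",
]


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest counts for a single class; partitions the total sample."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class PRCurve:
    """Precision-recall points (recall nondecreasing) and average precision."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    area: float


@dataclass
class EvaluationReport:
    """Per-class and aggregate metrics for one model on one test set.

    ``warnings`` flags per-class 0/0 metric cells (empty true or predicted
    class) that were reported as 0.
    """

    matrix: np.ndarray
    supports: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float
    weighted: dict[str, float]
    macro: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    class_names: tuple[str, ...] = CLASS_NAMES


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], C: int
) -> np.ndarray:
    """``counts[i, j]`` = number of beats of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= C or y_pred.min() < 0 or y_pred.max() >= C
    ):
        raise ValueError(f"labels out of range [0, {C})")
    m = np.zeros((C, C), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def one_vs_rest_counts(m: np.ndarray, cls: int) -> ClassCounts:
    """Reduce a confusion matrix to TP/FP/TN/FN for one class."""
    m = np.asarray(m)
    C = m.shape[0]
    if not 0 <= cls < C:
        raise ValueError(f"class index {cls} out of range [0, {C})")
    tp = int(m[cls, cls])
    fn = int(m[cls].sum()) - tp
    fp = int(m[:, cls].sum()) - tp
    tn = int(m.sum()) - tp - fn - fp
    return ClassCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def report(m: np.ndarray, class_names: Sequence[str] | None = None) -> EvaluationReport:
    """Per-class and aggregate ACC/RE/PR/SP/F1 from a confusion matrix.

    0/0 cells are reported as 0 and flagged in ``warnings``; aggregates are
    support-weighted means (macro means included for reference).
    """
    m = np.asarray(m, dtype=np.int64)
    C = m.shape[0]
    total = int(m.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    names = tuple(class_names) if class_names is not None else (
        CLASS_NAMES if C == len(CLASS_NAMES) else tuple(str(i) for i in range(C))
    )
    supports = m.sum(axis=1)
    re = np.zeros(C)
    pr = np.zeros(C)
    sp = np.zeros(C)
    f1 = np.zeros(C)
    warnings: list[str] = []
    for c in range(C):
        counts = one_vs_rest_counts(m, c)
        re[c], w1 = _safe_div(counts.TP, counts.TP + counts.FN)
        pr[c], w2 = _safe_div(counts.TP, counts.TP + counts.FP)
        sp[c], w3 = _safe_div(counts.TN, counts.TN + counts.FP)
        f1[c], w4 = _safe_div(2.0 * re[c] * pr[c], re[c] + pr[c])
        for flag, metric in ((w1, "RE"), (w2, "PR"), (w3, "SP"), (w4, "F1")):
            if flag:
                warnings.append(f"{names[c]}: {metric} is 0/0, reported as 0")
    weights = supports / total
    weighted = {
        "RE": float(weights @ re),
        "PR": float(weights @ pr),
        "SP": float(weights @ sp),
        "F1": float(weights @ f1),
    }
    macro = {
        "RE": float(re.mean()),
        "PR": float(pr.mean()),
        "SP": float(sp.mean()),
        "F1": float(f1.mean()),
    }
    return EvaluationReport(
        matrix=m,
        supports=supports,
        recall=re,
        precision=pr,
        specificity=sp,
        f1=f1,
        accuracy=float(np.trace(m) / total),
        weighted=weighted,
        macro=macro,
        warnings=warnings,
        class_names=names,
    )


def pr_curve(y_true_binary: Sequence[int], scores: Sequence[float]) -> PRCurve:
    """One-vs-rest precision-recall curve with average-precision area.

    One point per distinct score threshold (descending); at each threshold
    the positives are the items scoring at or above it.  The area is the
    step-wise average precision ``Σ ΔR·P``, invariant to strictly monotone
    transformations of the scores.
    """
    y = np.asarray(y_true_binary, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("pr_curve needs at least one positive example")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    pred_pos = np.arange(1, y.size + 1)
    # keep only the last item of each tied-score block
    distinct = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tp = tp_cum[distinct].astype(float)
    pp = pred_pos[distinct].astype(float)
    thresholds = s_sorted[distinct]
    recall = tp / n_pos
    precision = tp / pp
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    area = float(np.sum((recall - prev_recall) * precision))
    return PRCurve(
        recall=recall, precision=precision, thresholds=thresholds, area=area
    )


def pr_curves_from_probs(
    y_true: Sequence[int], probs: np.ndarray
) -> dict[int, PRCurve]:
    """Per-class PR curves from a label vector and a probability matrix.

    Classes with no positive examples are omitted.
    """
    y_true = np.asarray(y_true, dtype=int)
    probs = np.atleast_2d(probs)
    out: dict[int, PRCurve] = {}
    for c in range(probs.shape[1]):
        binary = (y_true == c).astype(int)
        if binary.sum() == 0:
            continue
        out[c] = pr_curve(binary, probs[:, c])
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_report_csv(path: str | Path, rep: EvaluationReport) -> Path:
    """Per-class rows plus weighted and macro aggregate rows."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "support", "ACC", "RE", "SP", "PR", "F1"])
        for c, name in enumerate(rep.class_names):
            w.writerow(
                [
                    name,
                    int(rep.supports[c]),
                    "",
                    f"{rep.recall[c]:.6f}",
                    f"{rep.specificity[c]:.6f}",
                    f"{rep.precision[c]:.6f}",
                    f"{rep.f1[c]:.6f}",
                ]
            )
        for label, agg in (("weighted", rep.weighted), ("macro", rep.macro)):
            w.writerow(
                [
                    label,
                    int(rep.supports.sum()),
                    f"{rep.accuracy:.6f}" if label == "weighted" else "",
                    f"{agg['RE']:.6f}",
                    f"{agg['SP']:.6f}",
                    f"{agg['PR']:.6f}",
                    f"{agg['F1']:.6f}",
                ]
            )
    return path


def write_confusion_text(path: str | Path, rep: EvaluationReport) -> Path:
    path = Path(path)
    names = rep.class_names
    width = max(6, max(len(n) for n in names) + 1)
    with path.open("w") as fh:
        fh.write("true\\pred".ljust(width + 3))
        fh.write("".join(n.rjust(width) for n in names) + "\n")
        for c, name in enumerate(names):
            fh.write(name.ljust(width + 3))
            fh.write("".join(str(int(v)).rjust(width) for v in rep.matrix[c]) + "\n")
    return path


def write_pr_curve_csv(path: str | Path, curve: PRCurve) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "recall", "precision"])
        for thr, r, p in zip(curve.thresholds, curve.recall, curve.precision):
            w.writerow([f"{thr:.10g}", f"{r:.10g}", f"{p:.10g}"])
        w.writerow(["area", f"{curve.area:.10g}", ""])
    return path
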