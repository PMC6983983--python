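"""Confusion matrices, CCR and per-class/macro performance measures.

Per-class measures follow the standard one-vs-rest decomposition of a
multiclass confusion matrix:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    f-score     = 2*TP / (2*TP + FP + FN)

"Average" measures are unweighted (macro) means across classes.  The
package ships the reference confusion matrices published for the seven
Rfam riboswitch families (LDA, PNN, decision tree, KNN under 10-fold CV
on block-location features); their printed TP/FP/TN/FN rows are loaded
verbatim rather than re-derived, because the published per-class
denominators demonstrably follow those rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

_MEASURES = ("accuracy", "sensitivity", "specificity", "f_score")


@dataclass
class ConfusionStats:
    """Square predicted-vs-true count matrix plus per-class TP/FP/TN/FN.

    ``counts[p, t]`` is the number of observations predicted as class p
    whose true class is t.  When built from predictions the one-vs-rest
    counts are derived from the matrix; when loaded from a reference table
    they are taken verbatim from its printed rows.
    """

    classes: list[str]
    counts: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"ConfusionStats: counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("ConfusionStats: negative count")
        for name in ("tp", "fp", "tn", "fn"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (k,) or np.any(arr < 0):
                raise ValueError(f"ConfusionStats: bad {name} row")
            setattr(self, name, arr)

    def _index(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise KeyError(f"unknown class {cls!r}") from None


def confusion_from_predictions(true_labels: Sequence[str], predicted_labels: Sequence[str],
                               classes: Sequence[str]) -> ConfusionStats:
    """Tabulate predictions into a ConfusionStats with derived TP/FP/TN/FN."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("confusion_from_predictions: label vectors differ in length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"true label {t!r} outside classes")
        if p not in index:
            raise ValueError(f"predicted label {p!r} outside classes")
        counts[index[p], index[t]] += 1
    tp = np.diag(counts).copy()
    fp = counts.sum(axis=1) - tp
    fn = counts.sum(axis=0) - tp
    tn = counts.sum() - tp - fp - fn
    return ConfusionStats(classes=classes, counts=counts, tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, measure: str, cls: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{measure} undefined for class {cls!r}: zero denominator")
    return num / den


def accuracy(stats: ConfusionStats, cls: str) -> float:
    i = stats._index(cls)
    return _ratio(stats.tp[i] + stats.tn[i],
                  stats.tp[i] + stats.fp[i] + stats.tn[i] + stats.fn[i], "accuracy", cls)


def sensitivity(stats: ConfusionStats, cls: str) -> float:
    i = stats._index(cls)
    return _ratio(stats.tp[i], stats.tp[i] + stats.fn[i], "sensitivity", cls)


def specificity(stats: ConfusionStats, cls: str) -> float:
    i = stats._index(cls)
    return _ratio(stats.tn[i], stats.fp[i] + stats.tn[i], "specificity", cls)


def f_score(stats: ConfusionStats, cls: str) -> float:
    i = stats._index(cls)
    return _ratio(2 * stats.tp[i], 2 * stats.tp[i] + stats.fp[i] + stats.fn[i], "f_score", cls)


def ccr(stats: ConfusionStats) -> float:
    """Correct classification rate: trace/total of the count matrix."""
    total = stats.counts.sum()
    if total == 0:
        raise ZeroDivisionError("ccr undefined: empty confusion matrix")
    return float(np.trace(stats.counts) / total)


@dataclass
class PerformanceReport:
    """Per-class and macro-averaged measures plus the overall CCR."""

    classes: list[str]
    accuracy: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    f_score: dict[str, float]
    macro_accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_f_score: float
    ccr: float


def macro_average(stats: ConfusionStats) -> PerformanceReport:
    """Per-class measures and their unweighted means across classes."""
    if not stats.classes:
        raise ValueError("macro_average: no classes")
    per = {m: {} for m in _MEASURES}
    fns = dict(accuracy=accuracy, sensitivity=sensitivity,
               specificity=specificity, f_score=f_score)
    for cls in stats.classes:
        for m in _MEASURES:
            per[m][cls] = fns[m](stats, cls)
    return PerformanceReport(
        classes=list(stats.classes),
        accuracy=per["accuracy"],
        sensitivity=per["sensitivity"],
        specificity=per["specificity"],
        f_score=per["f_score"],
        macro_accuracy=float(np.mean(list(per["accuracy"].values()))),
        macro_sensitivity=float(np.mean(list(per["sensitivity"].values()))),
        macro_specificity=float(np.mean(list(per["specificity"].values()))),
        macro_f_score=float(np.mean(list(per["f_score"].values()))),
        ccr=ccr(stats),
    )


# --------------------------------------------------------------------------
# Packaged reference confusion matrices (Rfam riboswitch study)
# --------------------------------------------------------------------------

REFERENCE_CLASSIFIERS = ("lda", "pnn", "tree", "knn")


def _data_path(name: str):
    return resources.files("riboblock.data").joinpath(name)


def load_reference_confusion(kind: str) -> ConfusionStats:
    """Load one of the packaged reference confusion matrices.

    ``kind`` is one of lda/pnn/tree/knn.  The TP/FP/TN/FN rows are taken
    verbatim from the table, not re-derived from the 7x7 counts.
    """
    if kind not in REFERENCE_CLASSIFIERS:
        raise ValueError(f"unknown reference classifier {kind!r}")
    rows: list[list[str]] = []
    with _data_path(f"confusion_{kind}.tsv").open() as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r]
    classes = rows[0][1:]
    k = len(classes)
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:1 + k]], dtype=int)
    extra = {r[0]: np.array([int(v) for v in r[1:]], dtype=int) for r in rows[1 + k:]}
    return ConfusionStats(classes=classes, counts=counts,
                          tp=extra["TP"], fp=extra["FP"], tn=extra["TN"], fn=extra["FN"])


@dataclass(frozen=True)
class ReferenceCheck:
    """One recomputed reference value compared with its recorded number."""

    classifier: str
    measure: str
    cls: str
    expected_percent: float
    computed_percent: float
    strict: bool

    @property
    def passed(self) -> bool:
        # strict rows must reproduce the recorded value to its printed
        # precision; info rows (strict=False) only report the difference
        if not self.strict:
            return True
        return abs(self.computed_percent - self.expected_percent) < 0.005 + 1e-9


def load_reference_metrics() -> list[tuple[str, str, str, float, bool]]:
    """Recorded published performance numbers: (classifier, measure, class, %, strict)."""
    out = []
    with _data_path("reference_metrics.tsv").open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            if not row:
                continue
            clf, measure, cls, val, strict = row
            out.append((clf, measure, cls, float(val), strict == "1"))
    return out


def check_reference() -> list[ReferenceCheck]:
    """Recompute every recorded reference number from the packaged tables."""
    stats = {kind: load_reference_confusion(kind) for kind in REFERENCE_CLASSIFIERS}
    fns = dict(accuracy=accuracy, sensitivity=sensitivity,
               specificity=specificity, f_score=f_score)
    checks: list[ReferenceCheck] = []
    for clf, measure, cls, expected, strict in load_reference_metrics():
        st = stats[clf]
        if measure == "ccr":
            computed = ccr(st) * 100.0
        elif cls == "macro":
            report = macro_average(st)
            computed = getattr(report, f"macro_{measure}") * 100.0
        else:
            computed = fns[measure](st, cls) * 100.0
        checks.append(ReferenceCheck(classifier=clf, measure=measure, cls=cls,
                                     expected_percent=expected,
                                     computed_percent=round(computed, 2), strict=strict))
    return checks
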