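"""Macro-averaged multiclass evaluation suite.

Per-class recall and precision are computed from a C x C confusion matrix
(rows = true class, columns = predicted class) and averaged without class
weighting (macro).  MF1 is the harmonic mean of MPre and MRec.  The
geometric mean GM is the C-th root of the product of per-class
sensitivities (sensitivity == recall); a single zero sensitivity would
collapse GM to zero, so zeros are floored at 0.001 before the product.
Undefined per-class ratios (empty row or column) are reported as 0 with a
logged warning rather than NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "macro_recall",
    "macro_precision",
    "mf1",
    "accuracy",
    "geometric_mean",
    "full_report",
]

log = logging.getLogger(__name__)

GM_FLOOR = 0.001


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) nonnegative ints; rows true, cols predicted

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("confusion matrix must be square and nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    per_class_recall: tuple[float, ...]
    per_class_precision: tuple[float, ...]
    mpre: float
    mrec: float
    mf1: float
    acc: float
    gm: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_csv_row(self) -> str:
        """One CSV row in the column order Acc, MPre, MRec, MF1, GM."""
        header = "Acc,MPre,MRec,MF1,GM"
        row = f"{self.acc:.6f},{self.mpre:.6f},{self.mrec:.6f},{self.mf1:.6f},{self.gm:.6f}"
        return header + "\n" + row + "\n"


def confusion(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    """counts[c, k] = number of samples with true class c predicted as k."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("labels out of range [0, n_classes)")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def macro_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class recall TP_c / (TP_c + FN_c) and its unweighted mean."""
    counts = cm.counts.astype(np.float64)
    row = counts.sum(axis=1)
    rec = np.zeros(cm.n_classes)
    for c in range(cm.n_classes):
        if row[c] == 0:
            log.warning("class %d has no true samples; recall set to 0", c)
        else:
            rec[c] = counts[c, c] / row[c]
    return rec, float(rec.mean())


def macro_precision(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class precision TP_c / (TP_c + FP_c) and its unweighted mean."""
    counts = cm.counts.astype(np.float64)
    col = counts.sum(axis=0)
    pre = np.zeros(cm.n_classes)
    for c in range(cm.n_classes):
        if col[c] == 0:
            log.warning("class %d never predicted; precision set to 0", c)
        else:
            pre[c] = counts[c, c] / col[c]
    return pre, float(pre.mean())


def mf1(mpre: float, mrec: float) -> float:
    """Harmonic mean of macro precision and macro recall."""
    if mpre == 0 and mrec == 0:
        return 0.0
    return 2.0 * mpre * mrec / (mpre + mrec)


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total count."""
    n = cm.n_samples
    return float(np.trace(cm.counts)) / n if n else 0.0


def geometric_mean(cm: ConfusionMatrix, floor: float = GM_FLOOR) -> float:
    """C-th root of the product of per-class sensitivities.

    Zero sensitivities are replaced by `floor` (default 0.001) so a single
    empty class does not collapse the statistic to zero.
    """
    sens, _ = macro_recall(cm)
    sens = np.where(sens == 0.0, floor, sens)
    # log-domain product for numerical safety
    return float(np.exp(np.log(sens).mean()))


def full_report(true_labels, predicted_labels, n_classes: int) -> MetricsReport:
    cm = confusion(true_labels, predicted_labels, n_classes)
    rec, mr = macro_recall(cm)
    pre, mp = macro_precision(cm)
    return MetricsReport(
        per_class_recall=tuple(float(x) for x in rec),
        per_class_precision=tuple(float(x) for x in pre),
        mpre=mp, mrec=mr, mf1=mf1(mp, mr), acc=accuracy(cm),
        gm=geometric_mean(cm))
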