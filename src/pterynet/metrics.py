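"""Segmentation and classification evaluation indicators.

Segmentation quality is scored from a pooled pixel confusion matrix
``p[i, j]`` (true class i, predicted class j, over the k+1 classes including
background, micro-averaged over a dataset):

* ``IOU_i  = p_ii / (sum_j p_ij + sum_j p_ji - p_ii)`` — intersection over union,
* ``MIOU   = mean_i IOU_i`` over the k+1 classes,
* ``PA     = sum_i p_ii / sum_ij p_ij`` — overall pixel accuracy,
* ``MPA    = mean_i (p_ii / sum_j p_ij)`` — mean per-class pixel accuracy.

A class absent from both prediction and truth (empty union) contributes 1 to
the means by convention — the "nothing to find, nothing found" case.

Image-level screening is scored from a 2x2 confusion matrix over
(normal, pterygium): per-class sensitivity (= recall), specificity (= the
other class's recall), F1 (harmonic mean of precision and recall), overall
accuracy, Cohen's kappa, and the single-operating-point AUC — the area under
the two-segment ROC through (0,0), (1-specificity, sensitivity), (1,1),
which reduces to (sensitivity + specificity) / 2.  Hard-label classifiers
have exactly one operating point, so this is the AUC their ROC supports.

Displayed values round half-up to two decimals.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess_io import LABELS, DimensionMismatchError, SegMask


class UndefinedMetricError(ValueError):
    """An indicator is undefined for this confusion matrix (empty margin)."""


# ---------------------------------------------------------------------------
# pixel-level (segmentation)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PixelConfusion:
    """Pixel counts p[i, j]: true class i, predicted class j; k+1 classes."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {m.shape}")
        if (m < 0).any():
            raise ValueError("confusion counts must be >= 0")
        self.matrix = m

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        """Number of non-background classes."""
        return self.n_classes - 1

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(self.matrix + other.matrix)


@dataclasses.dataclass
class SegMetricReport:
    iou: float    # lesion (foreground) class
    miou: float
    pa: float
    mpa: float
    per_class_iou: tuple[float, ...] = ()

    def as_percent(self) -> dict[str, float]:
        return {k: round_half_up(100 * v) for k, v in
                (("miou", self.miou), ("iou", self.iou),
                 ("mpa", self.mpa), ("pa", self.pa))}


def pixel_confusion(pred: SegMask, truth: SegMask) -> PixelConfusion:
    """Exact 2x2 pixel counts for a binary mask pair."""
    if (pred.height, pred.width) != (truth.height, truth.width):
        raise DimensionMismatchError(
            f"pred {pred.height}x{pred.width} vs truth {truth.height}x{truth.width}")
    idx = truth.pixels.astype(np.int64) * 2 + pred.pixels.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=4)
    return PixelConfusion(counts.reshape(2, 2))


def seg_metrics(pc: PixelConfusion) -> SegMetricReport:
    """IOU / MIOU / PA / MPA from pooled pixel counts (exact integer sums)."""
    m = pc.matrix
    if pc.total == 0:
        raise UndefinedMetricError("zero total pixels")
    diag = np.diag(m)
    row = m.sum(axis=1)   # truth totals g_i
    col = m.sum(axis=0)   # prediction totals p_i
    union = row + col - diag
    ious = np.where(union > 0, diag / np.maximum(union, 1), 1.0)   # empty-union -> 1
    accs = np.where(row > 0, diag / np.maximum(row, 1), 1.0)
    pa = float(diag.sum() / m.sum())
    return SegMetricReport(iou=float(ious[-1]), miou=float(ious.mean()),
                           pa=pa, mpa=float(accs.mean()),
                           per_class_iou=tuple(float(v) for v in ious))


def seg_metrics_dataset(pairs) -> SegMetricReport:
    """Micro-average: sum pixel confusions over (pred, truth) pairs, then score."""
    total: PixelConfusion | None = None
    for pred, truth in pairs:
        pc = pixel_confusion(pred, truth)
        total = pc if total is None else total + pc
    if total is None:
        raise UndefinedMetricError("no mask pairs to evaluate")
    return seg_metrics(total)


# ---------------------------------------------------------------------------
# image-level (classification)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionMatrix2x2:
    """Counts (true x predicted) over (normal, pterygium).

    ``n_tt`` true-normal predicted-normal, ``n_tf`` true-normal predicted-
    pterygium, ``n_ft`` true-pterygium predicted-normal, ``n_ff`` both
    pterygium — i.e. row = clinical truth, column = model diagnosis.
    """

    n_tt: int
    n_tf: int
    n_ft: int
    n_ff: int

    def __post_init__(self):
        if min(self.n_tt, self.n_tf, self.n_ft, self.n_ff) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.n_tt, self.n_tf], [self.n_ft, self.n_ff]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.n_tt + self.n_tf + self.n_ft + self.n_ff


@dataclasses.dataclass
class ClassReport:
    """Per-class screening indicators; undefined entries are ``None``."""

    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    f1: dict[str, float | None]
    accuracy: float
    kappa: float | None
    auc: float | None
    roc_points: dict[str, list[tuple[float, float]]]

    def require(self, indicator: str, cls: str | None = None) -> float:
        value = getattr(self, indicator)
        if isinstance(value, dict):
            value = value[cls]
        if value is None:
            raise UndefinedMetricError(
                f"{indicator} undefined" + (f" for class {cls}" if cls else ""))
        return value

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in LABELS:
            rows.append({
                "class": cls,
                "sensitivity_pct": _pct(self.sensitivity[cls]),
                "specificity_pct": _pct(self.specificity[cls]),
                "f1_pct": _pct(self.f1[cls]),
                "accuracy_pct": _pct(self.accuracy),
                "kappa_pct": _pct(self.kappa),
                "auc": None if self.auc is None else round_half_up(self.auc),
            })
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_roc_csv(self, path: str | Path) -> None:
        rows = [{"class": cls, "fpr": fpr, "tpr": tpr}
                for cls, pts in self.roc_points.items() for fpr, tpr in pts]
        pd.DataFrame(rows).to_csv(path, index=False)

    def format_table(self) -> str:
        """Plain-text layout mirroring a per-model column of the result table."""
        lines = [f"{'indicator':<22}{'normal':>10}{'pterygium':>12}"]
        for name, d in (("Sensitivity", self.sensitivity),
                        ("Specificity", self.specificity),
                        ("F1-score", self.f1)):
            lines.append(f"{name:<22}" + "".join(
                f"{_fmt_pct(d[c]):>10}" if c == LABELS[0] else f"{_fmt_pct(d[c]):>12}"
                for c in LABELS))
        auc = "n/a" if self.auc is None else f"{round_half_up(self.auc):.2f}"
        kappa = "n/a" if self.kappa is None else f"{_pct(self.kappa):.2f}%"
        lines.append(f"{'AUC':<22}{auc:>10}")
        lines.append(f"{'Kappa':<22}{kappa:>10}")
        lines.append(f"{'Accuracy':<22}{_pct(self.accuracy):.2f}%")
        return "\n".join(lines)


def round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(x: float | None) -> float | None:
    return None if x is None else round_half_up(100.0 * x)


def _fmt_pct(x: float | None) -> str:
    return "n/a" if x is None else f"{_pct(x):.2f}%"


def class_confusion(truths, preds) -> ConfusionMatrix2x2:
    """Count a 2x2 confusion matrix from parallel label sequences."""
    truths, preds = list(truths), list(preds)
    if len(truths) != len(preds):
        raise ValueError("label sequences differ in length")
    counts = np.zeros((2, 2), dtype=np.int64)
    index = {label: i for i, label in enumerate(LABELS)}
    for t, p in zip(truths, preds):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix2x2(*counts.ravel().tolist())


def class_report(cm: ConfusionMatrix2x2) -> ClassReport:
    """All screening indicators from one hard-label 2x2 confusion matrix."""
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    m = cm.matrix
    truth_tot = m.sum(axis=1)   # per true class
    pred_tot = m.sum(axis=0)    # per predicted class
    n = cm.total

    def recall(i: int) -> float | None:
        return None if truth_tot[i] == 0 else float(m[i, i] / truth_tot[i])

    def precision(i: int) -> float | None:
        return None if pred_tot[i] == 0 else float(m[i, i] / pred_tot[i])

    sens = {LABELS[i]: recall(i) for i in range(2)}
    spec = {LABELS[0]: sens[LABELS[1]], LABELS[1]: sens[LABELS[0]]}
    f1 = {}
    for i, cls in enumerate(LABELS):
        p, r = precision(i), recall(i)
        if p is None or r is None or (p + r) == 0:
            f1[cls] = None
        else:
            f1[cls] = 2 * p * r / (p + r)
    accuracy = float(np.trace(m) / n)
    p_e = float((truth_tot * pred_tot).sum() / (n * n))
    kappa = None if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    s_p, s_n = sens[LABELS[1]], sens[LABELS[0]]
    auc = None if (s_p is None or s_n is None) else (s_p + s_n) / 2.0
    roc = {}
    for cls in LABELS:
        if sens[cls] is None or spec[cls] is None:
            roc[cls] = [(0.0, 0.0), (1.0, 1.0)]
        else:
            roc[cls] = [(0.0, 0.0), (1.0 - spec[cls], sens[cls]), (1.0, 1.0)]
    return ClassReport(sensitivity=sens, specificity=spec, f1=f1,
                       accuracy=accuracy, kappa=kappa, auc=auc, roc_points=roc)


def reports_to_csv(reports: dict[str, ClassReport], path: str | Path) -> None:
    """One CSV row per model/class for a dict of named reports."""
    frames = []
    for model_name, report in reports.items():
        frame = report.to_frame()
        frame.insert(0, "model", model_name)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
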