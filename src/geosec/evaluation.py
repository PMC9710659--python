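"""Evaluation: macro metrics, boundary errors, element statistics.

Macro precision/recall average the per-class ratios uniformly over *all*
d classes of the scheme — a class absent from the test set contributes 0
— and F1 is the harmonic mean of the macro averages:

    R = (1/d) sum_i R_i,   P = (1/d) sum_i P_i,   F1 = 2 R P / (R + P).

(Note this is the harmonic mean of macro P and macro R, not the mean of
per-class F1 scores.)

The boundary-error profile localizes misclassifications within true
alpha/beta elements by their distance-to-extremity w (the first/last
residue of an element has w = 1), quantifying how much of the error mass
sits at element limits, where the backbone geometry deforms continuously
while reference labels jump discretely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .structure_io import ELEMENT_CLASSES, OTHER_CLASS, LabelSet


@dataclass
class MetricsReport:
    """Per-class and macro precision/recall/F1 plus the confusion matrix."""

    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # confusion[i, j] = count(true=i, pred=j)
    n_classes: int

    def summary(self) -> str:
        lines = [
            f"classes: {self.n_classes}",
            f"macro precision: {self.macro_precision:.4f}",
            f"macro recall:    {self.macro_recall:.4f}",
            f"macro F1:        {self.macro_f1:.4f}",
        ]
        for i in range(self.n_classes):
            lines.append(
                f"  class {i}: P={self.per_class_precision[i]:.4f} "
                f"R={self.per_class_recall[i]:.4f}"
            )
        return "\n".join(lines)


def _check_pair(true: LabelSet, pred: LabelSet) -> None:
    if true.scheme != pred.scheme:
        raise ValidationError("label schemes differ")
    if len(true) != len(pred):
        raise ValidationError("label lengths differ")


def macro_prf(true: LabelSet, pred: LabelSet) -> MetricsReport:
    """Macro-averaged precision, recall and F1 over all scheme classes."""
    _check_pair(true, pred)
    d = true.n_classes
    confusion = np.zeros((d, d), dtype=int)
    np.add.at(confusion, (true.labels, pred.labels), 1)
    diag = np.diag(confusion).astype(float)
    pred_totals = confusion.sum(axis=0).astype(float)
    true_totals = confusion.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, diag / pred_totals, 0.0)
        recall = np.where(true_totals > 0, diag / true_totals, 0.0)
    P = float(precision.mean())
    R = float(recall.mean())
    f1 = 2.0 * P * R / (P + R) if (P + R) > 0 else 0.0
    return MetricsReport(
        per_class_precision=precision,
        per_class_recall=recall,
        macro_precision=P,
        macro_recall=R,
        macro_f1=float(f1),
        confusion=confusion,
        n_classes=d,
    )


@dataclass
class ElementSpan:
    """A maximal run of one class: [start, end) residue list indices."""

    ss_class: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("element span must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


def segment_elements(labels: LabelSet, classes=None) -> list[ElementSpan]:
    """Maximal-run segmentation; optionally restricted to given class ids."""
    wanted = set(classes) if classes is not None else None
    spans = []
    arr = labels.labels
    i = 0
    while i < len(arr):
        j = i
        while j < len(arr) and arr[j] == arr[i]:
            j += 1
        if wanted is None or int(arr[i]) in wanted:
            spans.append(ElementSpan(ss_class=int(arr[i]), start=i, end=j))
        i = j
    return spans


def boundary_error_profile(
    true: LabelSet, pred: LabelSet, w_max: int = 2
) -> dict:
    """Histogram of misclassifications by distance-to-extremity w.

    For every misclassified residue inside a true alpha/beta element,
    w = 1 + min(offset from element start, offset from element end);
    buckets run over w in {1..w_max}, with deeper errors under
    ``"interior"`` and errors outside any element under ``"outside"``.
    """
    _check_pair(true, pred)
    element_ids = set(ELEMENT_CLASSES[true.scheme])
    hist: dict = {w: 0 for w in range(1, w_max + 1)}
    hist["interior"] = 0
    hist["outside"] = 0
    in_element = np.zeros(len(true), dtype=bool)
    for span in segment_elements(true, element_ids):
        in_element[span.start:span.end] = True
        for pos in range(span.start, span.end):
            if true.labels[pos] == pred.labels[pos]:
                continue
            w = 1 + min(pos - span.start, span.end - 1 - pos)
            if w <= w_max:
                hist[w] += 1
            else:
                hist["interior"] += 1
    errors = true.labels != pred.labels
    hist["outside"] = int(np.sum(errors & ~in_element))
    return hist


def element_stats(labels: LabelSet) -> dict:
    """Per element class: (element count, mean element length).

    Only alpha/beta elements are counted; Other runs are excluded.
    """
    out = {}
    for class_id, name in ELEMENT_CLASSES[labels.scheme].items():
        spans = segment_elements(labels, {class_id})
        if spans:
            out[name] = (len(spans), float(np.mean([len(sp) for sp in spans])))
        else:
            out[name] = (0, 0.0)
    return out


def trim_element_limits(labels: LabelSet, w: int = 1) -> LabelSet:
    """Relabel the first/last w residues of every alpha/beta element as
    Other; elements shorter than 2w+1 dissolve entirely.

    Used to re-score predictions with element limits excluded, since most
    disagreements with discrete reference labels sit at those limits.
    """
    if w < 1:
        raise ValidationError("w must be >= 1")
    other = OTHER_CLASS[labels.scheme]
    out = labels.labels.copy()
    for span in segment_elements(labels, set(ELEMENT_CLASSES[labels.scheme])):
        if len(span) < 2 * w + 1:
            out[span.start:span.end] = other
        else:
            out[span.start:span.start + w] = other
            out[span.end - w:span.end] = other
    return LabelSet(scheme=labels.scheme, labels=out)
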