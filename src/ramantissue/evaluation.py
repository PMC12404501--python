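"""Evaluation surface: confusion matrix, per-class metrics, precision-recall
curves with average precision, and the clinical-alert metric.

The clinical-alert (CA) metric targets the clinically costly error mode:
a malignant tissue class predicted as normal or benign. For a malignant
class ``c`` with diagonal entry ``TP_c`` and off-diagonal row sum
``FN_c``, the false negatives landing in *other malignant* columns
(``FNM_c``) are excluded — mistaking one sarcoma subtype for another
still raises an alert — leaving the clinical false negatives
``FNC_c = FN_c - FNM_c`` and

    CA_c = FNC_c / (TP_c + FN_c).

The overall CA pools numerators and denominators over the malignant
classes (micro average); the macro average (mean of per-class CA) is also
reported since either aggregation is defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix as _sk_confusion_matrix,
    precision_recall_curve,
)

__all__ = [
    "TissueOntology",
    "ConfusionMatrix",
    "MetricsReport",
    "ClinicalAlertReport",
    "OntologyError",
    "confusion_matrix",
    "per_class_metrics",
    "clinical_alert",
    "precision_recall",
]

CATEGORIES = ("normal", "benign", "malignant")


class OntologyError(ValueError):
    """Raised when an ontology cannot support the requested computation."""


@dataclass(frozen=True)
class TissueOntology:
    """Ordered tissue classes with their malignancy category.

    The default maps MSC/SKN/FAT to normal, LEM to benign, and
    MLS/PLS/LEI/HMS to malignant.
    """

    classes: Tuple[str, ...]
    category: Mapping[str, str]

    def __post_init__(self) -> None:
        for cls in self.classes:
            cat = self.category.get(cls)
            if cat not in CATEGORIES:
                raise OntologyError(
                    f"class {cls!r} has invalid category {cat!r}"
                )

    @classmethod
    def default(cls) -> "TissueOntology":
        return cls(
            classes=("MSC", "SKN", "FAT", "LEM", "MLS", "PLS", "LEI", "HMS"),
            category={
                "MSC": "normal", "SKN": "normal", "FAT": "normal",
                "LEM": "benign",
                "MLS": "malignant", "PLS": "malignant",
                "LEI": "malignant", "HMS": "malignant",
            },
        )

    @property
    def malignant_classes(self) -> Tuple[str, ...]:
        return tuple(c for c in self.classes if self.category[c] == "malignant")

    def to_dict(self) -> dict:
        return {"classes": list(self.classes),
                "category": {c: self.category[c] for c in self.classes}}

    @classmethod
    def from_dict(cls, d: dict) -> "TissueOntology":
        return cls(classes=tuple(d["classes"]), category=dict(d["category"]))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape does not match class list")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """Overall (weighted) accuracy = trace / total."""
        total = self.total
        return float(np.trace(self.counts)) / total if total else 0.0


@dataclass
class MetricsReport:
    """Per-class sensitivity/specificity/precision/F1 plus weighted averages.

    ``degenerate`` flags classes whose precision had a 0/0 cell (no
    predicted positives); by convention such cells report 0 rather than
    NaN so aggregates stay total.
    """

    per_class: Dict[str, Dict[str, float]]
    weighted: Dict[str, float]
    accuracy: float
    degenerate: List[str] = field(default_factory=list)


@dataclass
class ClinicalAlertReport:
    """Per-malignant-class TP/FN/FNM/FNC/CA and pooled aggregates."""

    per_class: Dict[str, Dict[str, float]]
    overall_ca: float          # micro: pooled FNC / pooled (TP + FN)
    overall_ca_macro: float    # mean of per-class CA values


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str],
                     ontology: Optional[TissueOntology] = None) -> ConfusionMatrix:
    """Count predictions into a K x K matrix in ontology class order."""
    ontology = ontology or TissueOntology.default()
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    known = set(ontology.classes)
    unknown = (set(y_true) | set(y_pred)) - known
    if unknown:
        raise KeyError(f"unknown label(s): {sorted(unknown)}")
    counts = _sk_confusion_matrix(y_true, y_pred, labels=list(ontology.classes))
    return ConfusionMatrix(counts=counts, classes=tuple(ontology.classes))


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, precision and F1 per class, from the matrix.

    sensitivity_c = TP_c / (TP_c + FN_c); specificity_c = TN_c / (TN_c + FP_c);
    precision_c = TP_c / (TP_c + FP_c). Weighted averages use per-class
    support (row sums) as weights.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)   # support
    col = counts.sum(axis=0).astype(float)   # predicted positives
    fn = row - tp
    fp = col - tp
    tn = total - row - fp

    degenerate: List[str] = []
    per_class: Dict[str, Dict[str, float]] = {}
    sens = np.zeros_like(tp)
    spec = np.zeros_like(tp)
    prec = np.zeros_like(tp)
    f1 = np.zeros_like(tp)
    for i, cls in enumerate(cm.classes):
        flagged = False
        if row[i] > 0:
            sens[i] = tp[i] / row[i]
        else:
            flagged = True
        if tn[i] + fp[i] > 0:
            spec[i] = tn[i] / (tn[i] + fp[i])
        else:
            flagged = True
        if col[i] > 0:
            prec[i] = tp[i] / col[i]
        else:
            flagged = True
        if prec[i] + sens[i] > 0:
            f1[i] = 2 * prec[i] * sens[i] / (prec[i] + sens[i])
        if flagged:
            degenerate.append(cls)
        per_class[cls] = {
            "sensitivity": float(sens[i]),
            "specificity": float(spec[i]),
            "precision": float(prec[i]),
            "f1": float(f1[i]),
            "support": int(row[i]),
        }
    support = row / total
    weighted = {
        "sensitivity": float(np.sum(support * sens)),
        "specificity": float(np.sum(support * spec)),
        "precision": float(np.sum(support * prec)),
        "f1": float(np.sum(support * f1)),
    }
    return MetricsReport(per_class=per_class, weighted=weighted,
                         accuracy=cm.accuracy(), degenerate=degenerate)


def clinical_alert(cm: ConfusionMatrix,
                   ontology: Optional[TissueOntology] = None) -> ClinicalAlertReport:
    """Clinical-alert metric: malignant classes misclassified as non-malignant.

    Per malignant class: ``FNC = FN - FNM`` and ``CA = FNC / (TP + FN)``,
    where FNM counts the false negatives predicted as *other malignant*
    classes. Classes with no test samples report CA 0.
    """
    ontology = ontology or TissueOntology.default()
    if tuple(ontology.classes) != tuple(cm.classes):
        raise OntologyError("ontology class order does not match the matrix")
    malignant = ontology.malignant_classes
    if not malignant:
        raise OntologyError("ontology has no malignant class")
    idx = {c: i for i, c in enumerate(cm.classes)}
    mal_cols = [idx[c] for c in malignant]

    per_class: Dict[str, Dict[str, float]] = {}
    pooled_fnc = 0.0
    pooled_total = 0.0
    cas: List[float] = []
    for cls in malignant:
        i = idx[cls]
        row = cm.counts[i].astype(float)
        tp = row[i]
        fn = row.sum() - tp
        fnm = sum(row[j] for j in mal_cols if j != i)
        fnc = fn - fnm
        denom = tp + fn
        ca = fnc / denom if denom > 0 else 0.0
        per_class[cls] = {
            "TP": int(tp), "FN": int(fn), "FNM": int(fnm), "FNC": int(fnc),
            "CA": float(ca),
        }
        pooled_fnc += fnc
        pooled_total += denom
        cas.append(ca)
    overall = pooled_fnc / pooled_total if pooled_total > 0 else 0.0
    return ClinicalAlertReport(
        per_class=per_class,
        overall_ca=float(overall),
        overall_ca_macro=float(np.mean(cas)),
    )


def precision_recall(scores: np.ndarray, y_true: Sequence[str],
                     classes: Optional[Sequence[str]] = None) -> Dict[str, dict]:
    """One-vs-rest precision-recall curve and average precision per class.

    ``scores`` is an (n, K) matrix of class probabilities in the order of
    ``classes``. AP is the step-wise sum over thresholds,
    ``sum_k (R_k - R_{k-1}) * P_k``. Classes absent from the truth are
    skipped with a warning.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = tuple(TissueOntology.default().classes)
    if scores.shape != (y_true.size, len(classes)):
        raise ValueError("scores shape does not match labels/classes")
    out: Dict[str, dict] = {}
    for j, cls in enumerate(classes):
        positives = y_true == cls
        if not np.any(positives):
            warnings.warn(f"class {cls!r} absent from truth; curve skipped")
            continue
        precision, recall, thresholds = precision_recall_curve(
            positives.astype(int), scores[:, j]
        )
        ap = float(average_precision_score(positives.astype(int), scores[:, j]))
        out[cls] = {
            "precision": precision,
            "recall": recall,
            "thresholds": thresholds,
            "average_precision": ap,
        }
    return out
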