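"""Evaluation arithmetic: confusion matrices, per-class rates, F-scores, AUC.

Conventions
-----------
* Confusion matrices are K×K integer arrays, rows = true class, columns =
  predicted class, in a caller-supplied canonical class order.
* Undefined ratios (zero denominators) are reported as ``nan`` and flagged,
  never silently zeroed.
* ROC-AUC uses the trapezoidal rule over all thresholds, equivalent to the
  Mann-Whitney statistic with ties counted 1/2. Multiclass AUC is
  one-vs-rest per class with an unweighted (macro) average over the classes
  for which both outcomes are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auc

from .taxonomy import TaxonomyError


def round_half_up(x: float, decimals: int = 4) -> float:
    """Decimal display rounding (0.5 always rounds away from zero)."""
    if math.isnan(x):
        return x
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     class_order: Sequence) -> np.ndarray:
    """counts[i, j] = #(true == class_order[i] and predicted == class_order[j])."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    known = set(class_order)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise TaxonomyError(f"label {lab!r} not in class order")
    return _sk_confusion(true_labels, predicted_labels, labels=list(class_order))


@dataclass(frozen=True)
class ClassRates:
    precision: float
    sensitivity: float
    specificity: float

    @property
    def defined(self) -> dict[str, bool]:
        return {k: not math.isnan(getattr(self, k))
                for k in ("precision", "sensitivity", "specificity")}


def class_metrics(cm: np.ndarray, k: int) -> ClassRates:
    """Precision, sensitivity and specificity of class ``k`` from a confusion matrix."""
    cm = np.asarray(cm)
    tp = cm[k, k]
    fp = cm[:, k].sum() - tp
    fn = cm[k, :].sum() - tp
    tn = cm.sum() - tp - fp - fn

    def _ratio(num, den):
        return float(num) / float(den) if den > 0 else float("nan")

    return ClassRates(
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
    )


def f_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean 2PR/(P+R); nan when undefined (P = R = 0 or nan inputs)."""
    if math.isnan(precision) or math.isnan(sensitivity):
        return float("nan")
    if precision == 0.0 and sensitivity == 0.0:
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def overall_accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm)) / float(total)


def roc_auc(binary_truth: Sequence, scores: Sequence) -> float:
    """Area under the ROC curve of a score for a binary outcome."""
    y = np.asarray(binary_truth).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC needs both outcome classes present")
    return float(_sk_auc(y, s))


def multiclass_auc(truth: Sequence, prediction_vectors: np.ndarray,
                   class_order: Sequence) -> tuple[dict, float]:
    """One-vs-rest AUC per class plus the macro (unweighted) average.

    Classes absent from the truth (or covering all of it) get ``nan`` and are
    excluded from the macro average.
    """
    probs = np.asarray(prediction_vectors, dtype=float)
    truth = list(truth)
    if probs.shape != (len(truth), len(class_order)):
        raise ValueError("prediction matrix shape does not match truth/classes")
    per_class: dict = {}
    present = []
    for j, cls in enumerate(class_order):
        y = np.asarray([t == cls for t in truth], dtype=int)
        if y.min() == y.max():
            per_class[cls] = float("nan")
            continue
        auc = roc_auc(y, probs[:, j])
        per_class[cls] = auc
        present.append(auc)
    if not present:
        raise ValueError("no class with both outcomes present")
    return per_class, float(np.mean(present))


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-class and aggregate metrics."""

    class_order: tuple
    cm: np.ndarray
    per_class: dict
    accuracy: float
    macro_auc: float | None

    @classmethod
    def from_predictions(cls, true_labels, predicted_labels, class_order,
                         prediction_vectors=None) -> "EvaluationReport":
        cm = confusion_matrix(true_labels, predicted_labels, class_order)
        aucs = {c: float("nan") for c in class_order}
        macro = None
        if prediction_vectors is not None:
            aucs, macro = multiclass_auc(true_labels, prediction_vectors, class_order)
        per_class = {}
        for k, cls_name in enumerate(class_order):
            rates = class_metrics(cm, k)
            per_class[cls_name] = {
                "precision": rates.precision,
                "sensitivity": rates.sensitivity,
                "specificity": rates.specificity,
                "f_score": f_score(rates.precision, rates.sensitivity),
                "auc": aucs[cls_name],
                "support": int(cm[k, :].sum()),
            }
        return cls(tuple(class_order), cm, per_class,
                   overall_accuracy(cm), macro)

    def to_dict(self) -> dict:
        def _clean(v):
            return None if (isinstance(v, float) and math.isnan(v)) else v
        return {
            "per_class": {c: {k: _clean(round_half_up(v) if isinstance(v, float) else v)
                              for k, v in d.items()}
                          for c, d in self.per_class.items()},
            "overall": {
                "accuracy": round_half_up(self.accuracy),
                "macro_auc": (round_half_up(self.macro_auc)
                              if self.macro_auc is not None else None),
            },
            "confusion_matrix": self.cm.tolist(),
            "class_order": list(self.class_order),
        }

    def macro_sensitivity(self) -> float:
        """Unweighted mean sensitivity over classes where it is defined."""
        vals = [d["sensitivity"] for d in self.per_class.values()
                if not math.isnan(d["sensitivity"])]
        return float(np.mean(vals))

    def summary(self) -> str:
        hdr = f"{'class':<22}{'prec':>8}{'sens':>8}{'spec':>8}{'F':>8}{'AUC':>8}{'n':>7}"
        lines = [hdr, "-" * len(hdr)]
        for c, d in self.per_class.items():
            def fmt(v):
                return "   nan" if math.isnan(v) else f"{v:6.4f}"
            lines.append(f"{c:<22}{fmt(d['precision']):>8}{fmt(d['sensitivity']):>8}"
                         f"{fmt(d['specificity']):>8}{fmt(d['f_score']):>8}"
                         f"{fmt(d['auc']):>8}{d['support']:>7}")
        lines.append(f"overall accuracy {self.accuracy:.4f}"
                     + (f", macro AUC {self.macro_auc:.4f}"
                        if self.macro_auc is not None else ""))
        return "\n".join(lines)
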