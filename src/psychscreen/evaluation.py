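"""Contingency-table evaluation: accuracy, precision, recall, balanced F.

Predicted and gold labels are compared patient-by-patient into TP/FP/FN/TN
counts; the four screening metrics follow. Undefined ratios (zero
denominators) are reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

Label = Union[str, bool, int]

_POSITIVE_LABELS = {"positive", "high", "1", "true", "yes"}
_NEGATIVE_LABELS = {"negative", "low", "0", "false", "no"}


class EvaluationError(ValueError):
    pass


def _as_bool(label: Label) -> bool:
    if isinstance(label, bool):
        return label
    if isinstance(label, (int, float)) and label in (0, 1):
        return bool(label)
    text = str(label).strip().lower()
    if text in _POSITIVE_LABELS:
        return True
    if text in _NEGATIVE_LABELS:
        return False
    raise EvaluationError(f"label {label!r} is not binary")


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f_measure: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n": self.n,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }

    def as_percents(self, digits: int = 0) -> dict:
        """Display form matching how screening studies print these metrics."""
        return {
            k: (round(100.0 * v, digits) if not math.isnan(v) else float("nan"))
            for k, v in (
                ("accuracy", self.accuracy),
                ("precision", self.precision),
                ("recall", self.recall),
                ("f_measure", self.f_measure),
            )
        }


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def f_measure(precision: float, recall: float) -> float:
    """Balanced (beta = 1) F-measure: the harmonic mean 2PR/(P+R)."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise EvaluationError(f"{name} must be in [0, 1], got {v}")
    if precision + recall == 0.0:
        warnings.warn("F-measure undefined (precision + recall = 0); reporting NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def contingency(
    predictions: Mapping[str, Label], gold: Mapping[str, Label]
) -> EvalReport:
    """Build the 2x2 contingency table and derived metrics.

    Raises when the two patient-id sets differ, listing the difference.
    """
    pred_ids, gold_ids = set(predictions), set(gold)
    if pred_ids != gold_ids:
        missing = sorted(gold_ids - pred_ids)
        extra = sorted(pred_ids - gold_ids)
        raise EvaluationError(
            f"patient id sets differ: missing predictions for {missing}, "
            f"predictions without gold label for {extra}"
        )
    tp = fp = fn = tn = 0
    for pid in predictions:
        p, g = _as_bool(predictions[pid]), _as_bool(gold[pid])
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    n = tp + fp + fn + tn
    accuracy = _ratio(tp + tn, n, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if math.isnan(precision) or math.isnan(recall):
        f = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = f_measure(precision, recall)
        if math.isnan(f):
            warnings.warn("F-measure undefined; reporting NaN", RuntimeWarning,
                          stacklevel=2)
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, accuracy=accuracy,
                      precision=precision, recall=recall, f_measure=f)


def threshold_sweep(
    tallies: Sequence,
    gold: Mapping[str, Label],
    thresholds: Iterable[int] = range(1, 23),
) -> pd.DataFrame:
    """Convenience extension: metrics at each positivity threshold.

    Not part of the screening procedure itself — a tuning aid that sweeps
    the distinct-term cutoff and reports the table row per threshold.
    """
    from .scoring import ClassifierConfig, classify_patient  # cycle guard

    rows = []
    for threshold in thresholds:
        cfg = ClassifierConfig(threshold=threshold)
        preds = {t.patient_id: classify_patient(t, cfg) for t in tallies}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            report = contingency(preds, gold)
        rows.append({"threshold": threshold, **report.to_dict()})
    return pd.DataFrame(rows)
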