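"""Agreement statistics between software and reference (visual) calls.

Expert visual reading is the reference: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/N.  Percentages are rounded
half-up to one decimal.  Undefined ratios (an empty class) are reported as
not-available, never as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["ConfusionSummary", "confusion_from_calls", "titer_concordance",
           "evaluate_calls_table"]

_POSITIVE = {"positive", "pos", "p", "1", "true"}
_NEGATIVE = {"negative", "neg", "n", "0", "false"}


def _as_bool(verdict) -> bool:
    if isinstance(verdict, bool):
        return verdict
    s = str(verdict).strip().lower()
    if s in _POSITIVE:
        return True
    if s in _NEGATIVE:
        return False
    raise ValueError(f"verdict not binary: {verdict!r}")


def _pct(value: float | None) -> float | None:
    if value is None:
        return None
    return float(
        Decimal(value * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class ConfusionSummary:
    """2x2 confusion counts of software vs reference calls."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def sensitivity_pct(self) -> float | None:
        return _pct(self.sensitivity)

    @property
    def specificity_pct(self) -> float | None:
        return _pct(self.specificity)

    @property
    def accuracy_pct(self) -> float | None:
        return _pct(self.accuracy)

    def to_dict(self) -> dict:
        def fmt(x):
            return "NA" if x is None else x

        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "total": self.total,
            "sensitivity_pct": fmt(self.sensitivity_pct),
            "specificity_pct": fmt(self.specificity_pct),
            "accuracy_pct": fmt(self.accuracy_pct),
        }

    def report(self) -> str:
        d = self.to_dict()
        return (
            f"n = {d['total']}\n"
            f"  software+ / reference+ (TP): {self.tp}\n"
            f"  software+ / reference- (FP): {self.fp}\n"
            f"  software- / reference+ (FN): {self.fn}\n"
            f"  software- / reference- (TN): {self.tn}\n"
            f"sensitivity: {d['sensitivity_pct']}%\n"
            f"specificity: {d['specificity_pct']}%\n"
            f"accuracy:    {d['accuracy_pct']}%"
        )


def confusion_from_calls(pairs) -> ConfusionSummary:
    """Count a list of (software_verdict, reference_verdict) pairs.

    Verdicts may be booleans or positive/negative strings.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one call pair is required")
    tp = fp = fn = tn = 0
    for software, reference in pairs:
        s, r = _as_bool(software), _as_bool(reference)
        if s and r:
            tp += 1
        elif s and not r:
            fp += 1
        elif not s and r:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def titer_concordance(pairs, tolerance: int = 1) -> float:
    """Fraction of (software_level, reference_level) pairs within tolerance.

    Levels are integer indices into the titer steps, with "negative" = -1.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one titer pair is required")
    hits = sum(1 for a, b in pairs if abs(int(a) - int(b)) <= tolerance)
    return hits / len(pairs)


def evaluate_calls_table(table: pd.DataFrame, tolerance: int = 1) -> dict:
    """Evaluate a calls table (software vs reference verdicts, optional titers).

    Required columns: ``software_verdict``, ``reference_verdict``; optional
    ``software_titer_level``/``reference_titer_level`` add the titer
    concordance fraction.
    """
    for col in ("software_verdict", "reference_verdict"):
        if col not in table.columns:
            raise KeyError(f"missing column: {col}")
    summary = confusion_from_calls(
        zip(table["software_verdict"], table["reference_verdict"])
    )
    out = summary.to_dict()
    if {"software_titer_level", "reference_titer_level"} <= set(table.columns):
        sub = table.dropna(subset=["software_titer_level", "reference_titer_level"])
        if len(sub):
            out["titer_concordance"] = titer_concordance(
                zip(sub["software_titer_level"], sub["reference_titer_level"]),
                tolerance,
            )
            out["titer_tolerance"] = tolerance
    return out
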