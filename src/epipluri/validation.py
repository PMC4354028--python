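"""Confusion-matrix metrics for score validation.

The positive class is *pluripotent*.  Sensitivity is the percentage of
pluripotent samples called pluripotent; specificity the percentage of
somatic samples called non-pluripotent.  Samples whose truth label is
neither pluripotent nor somatic (differentiated, parthenogenic, unknown)
are excluded from the counts, with the excluded total logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .exceptions import EpiPluriError
from .scoring import PLURIPOTENT

logger = logging.getLogger(__name__)

_EVALUATED_LABELS = ("pluripotent", "somatic")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EpiPluriError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    calls: Mapping[str, str],
    truth_labels: Mapping[str, str],
) -> ConfusionMatrix:
    """Count calls against truth, aligned by sample id.

    ``calls`` maps sample id -> {pluripotent, non_pluripotent}; ``truth``
    maps sample id -> class label.  Every call must have a truth label and
    every pluripotent/somatic truth sample must have a call; a mismatch is
    an error rather than a silent drop.
    """
    unmatched = sorted(set(calls) - set(truth_labels))
    if unmatched:
        raise EpiPluriError(f"calls without truth labels: {unmatched[:5]}")
    evaluated = {s: l for s, l in truth_labels.items() if l in _EVALUATED_LABELS}
    missing = sorted(set(evaluated) - set(calls))
    if missing:
        raise EpiPluriError(f"truth samples without calls: {missing[:5]}")
    excluded = len(set(calls) & (set(truth_labels) - set(evaluated)))
    if excluded:
        logger.info(
            "%d samples with non-pluripotent/non-somatic truth labels "
            "excluded from the confusion matrix", excluded,
        )
    tp = fp = tn = fn = 0
    for sample, label in evaluated.items():
        positive_call = calls[sample] == PLURIPOTENT
        if label == "pluripotent":
            tp += positive_call
            fn += not positive_call
        else:
            fp += positive_call
            tn += not positive_call
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> float | None:
    """Percent of true pluripotent samples recovered; None when undefined."""
    if cm.tp + cm.fn == 0:
        return None
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float | None:
    """Percent of true somatic samples rejected; None when undefined."""
    if cm.tn + cm.fp == 0:
        return None
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def format_percent(value: float | None) -> str:
    """Half-up rounding to one decimal for report strings ('98.9')."""
    if value is None:
        return "undefined"
    return str(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def metrics_json(cm: ConfusionMatrix) -> dict:
    """Machine-readable metrics: raw counts plus unrounded percentages."""
    return {
        "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
    }
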