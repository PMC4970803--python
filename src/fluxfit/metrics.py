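"""Confusion-matrix bookkeeping for growth/non-growth predictions.

Convention: "positive" means predicted growth.  tp = predicted growth &
observed growth, fp = predicted growth & observed non-growth, fn = predicted
non-growth & observed growth, tn = predicted non-growth & observed non-growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fba import GROWTH


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @staticmethod
    def from_labels(pairs: list[tuple[str, str]]) -> "ConfusionMatrix":
        """Build from (predicted, observed) label pairs."""
        tp = fp = fn = tn = 0
        for pred, obs in pairs:
            if pred == GROWTH and obs == GROWTH:
                tp += 1
            elif pred == GROWTH:
                fp += 1
            elif obs == GROWTH:
                fn += 1
            else:
                tn += 1
        return ConfusionMatrix(tp, fp, fn, tn)


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy (percent), MCC, sensitivity and specificity.

    MCC = (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any zero
    factor in the denominator yields MCC = 0 by convention.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = 0.0 if denom == 0 else (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    sensitivity = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return {
        "accuracy": accuracy,
        "mcc": mcc,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


def combine_matrices(matrices: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum, e.g. pooling knockout panels across media."""
    if not matrices:
        raise ValueError("need at least one confusion matrix")
    out = matrices[0]
    for cm in matrices[1:]:
        out = out + cm
    return out


def round_half_up(value: float, ndigits: int) -> float:
    """Round-half-up to the printed precision used in report tables."""
    factor = 10**ndigits
    return math.floor(value * factor + 0.5) / factor


def format_metrics(cm: ConfusionMatrix) -> str:
    m = classification_metrics(cm)
    return (
        f"tp={cm.tp}\tfp={cm.fp}\tfn={cm.fn}\ttn={cm.tn}\t"
        f"accuracy={round_half_up(m['accuracy'], 1):.1f}%\tmcc={round_half_up(m['mcc'], 2):.2f}"
    )
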