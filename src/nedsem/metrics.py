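"""Confusion-matrix segmentation metrics: accuracy, specificity, Jaccard, Dice.

Lesion pixels are the positive class and background the negative class.
Multi-label masks are binarized by a caller-supplied set of positive labels;
the default treats both the lesion core and the banded edge as lesion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: labels counted as lesion by default: banded edge (1) and core (2)
DEFAULT_POSITIVE = frozenset({1, 2})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Scores:
    acc: float
    sp: float
    ja: float
    dice: float

    def as_dict(self) -> dict:
        return {"Acc": self.acc, "SP": self.sp, "JA": self.ja, "Dice": self.dice}


def confusion(pred: np.ndarray, truth: np.ndarray,
              positive_labels: Iterable[int] = DEFAULT_POSITIVE) -> ConfusionCounts:
    """Exact pixel counts after binarizing both masks with `positive_labels`."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    pos = np.asarray(sorted(set(positive_labels)))
    p = np.isin(pred, pos)
    t = np.isin(truth, pos)
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator)", name)
        return math.nan
    return num / den


def scores(c: ConfusionCounts) -> Scores:
    """Acc, SP, JA and Dice from pixel counts; zero denominators give NaN."""
    if c.total <= 0:
        raise ValueError("no pixels evaluated")
    return Scores(
        acc=_ratio(c.tp + c.tn, c.total, "Acc"),
        sp=_ratio(c.tn, c.tn + c.fp, "SP"),
        ja=_ratio(c.tp, c.tp + c.fn + c.fp, "JA"),
        dice=_ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn, "Dice"),
    )


def binary_dice(pred: np.ndarray, truth: np.ndarray,
                positive_labels: Iterable[int]) -> float:
    """Convenience: Dice of one label set against the same set in truth."""
    return scores(confusion(pred, truth, positive_labels)).dice
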