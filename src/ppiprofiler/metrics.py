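"""Confusion-matrix bookkeeping and screening metrics (Se, Sp, EF).

The enrichment factor is the hit rate within the selected subset divided
by the hit rate under random selection:

    EF = [TP/(TP+FP)] / [(TP+FN)/N] = precision / active prevalence

equivalently Se divided by the selected fraction.  EF = 1 for random-rate
selection; the ceiling is N/(TP+FN), reached at perfect precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .errors import MetricError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_selected(self) -> int:
        return self.tp + self.fp

    @property
    def n_active(self) -> int:
        return self.tp + self.fn


def confusion(truth: Sequence[int], pred: Sequence[int]) -> ConfusionCounts:
    """2x2 tally of binary labels (1 = active/selected)."""
    if len(truth) != len(pred):
        raise MetricError("truth and prediction must have equal length")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, pred):
        if t not in (0, 1) or p not in (0, 1):
            raise MetricError("labels must be binary 0/1")
        if t and p:
            tp += 1
        elif t and not p:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def sensitivity(c: ConfusionCounts) -> float:
    """Se = TP/(TP+FN), in percent."""
    if c.tp + c.fn == 0:
        raise MetricError("sensitivity undefined: no actives (TP+FN = 0)")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Sp = TN/(TN+FP), in percent."""
    if c.tn + c.fp == 0:
        raise MetricError("specificity undefined: no inactives (TN+FP = 0)")
    return 100.0 * c.tn / (c.tn + c.fp)


def enrichment_factor(c: ConfusionCounts) -> float:
    """EF = precision / prevalence.

    An empty selection (TP+FP = 0) returns 0.0 with a warning — degenerate
    splits during tree induction need a defined value, and "no enrichment"
    is the honest one.  No actives at all (TP+FN = 0) is an error.
    """
    if c.n_active == 0:
        raise MetricError("enrichment undefined: no actives (TP+FN = 0)")
    if c.n_selected == 0:
        log.warning("empty selection: enrichment factor defined as 0")
        return 0.0
    precision = c.tp / c.n_selected
    prevalence = c.n_active / c.n
    return precision / prevalence


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero (report display convention)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def metrics_report(c: ConfusionCounts) -> dict:
    """Raw and display-rounded Se/Sp/EF for one counts object."""
    se, sp, ef = sensitivity(c), specificity(c), enrichment_factor(c)
    return {
        "TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn, "N": c.n,
        "Se": se, "Sp": sp, "EF": ef,
        "Se_display": int(round_half_up(se)),
        "Sp_display": int(round_half_up(sp)),
        "EF_display": round_half_up(ef, 2),
    }
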