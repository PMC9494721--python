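"""Detection scoring: site-vs-mask matching and TPR/FPR bookkeeping.

Counts may be fractional because replicate averages are first-class (a
mean over repeated fields of view yields non-integer TP/FN/FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scene_sim import GroundTruth

__all__ = ["EvalCounts", "EvalRates", "match_detections", "rates", "average_counts"]


@dataclass(frozen=True)
class EvalCounts:
    tp: float
    fn: float
    fp: float

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fn < 0 or self.fp < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class EvalRates:
    tpr: float  # percent
    fpr: float  # percent


def match_detections(
    sites: Sequence[tuple[float, float]], truth: GroundTruth
) -> EvalCounts:
    """Greedy one-to-one matching of detected sites to nucleus masks.

    A site hits a cell if it falls inside that cell's mask. The first hit
    on a cell is a true positive; further hits on the same cell are false
    positives (duplicate labels), as are sites landing in no mask
    (off-target). Cells never hit are false negatives.
    """
    matched = [False] * truth.cell_count
    tp = fp = 0
    for site in sites:
        r, c = int(round(site[0])), int(round(site[1]))
        hit = None
        for k, mask in enumerate(truth.nucleus_masks):
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
                hit = k
                break
        if hit is None:
            fp += 1
        elif matched[hit]:
            fp += 1
        else:
            matched[hit] = True
            tp += 1
    fn = truth.cell_count - tp
    return EvalCounts(tp=tp, fn=fn, fp=fp)


def rates(counts: EvalCounts) -> EvalRates:
    """TPR = 100 TP/(TP+FN), FPR = 100 FP/(TP+FN), in percent."""
    visible = counts.tp + counts.fn
    if visible <= 0:
        raise ValueError("TP + FN must be positive (no visible cells)")
    return EvalRates(tpr=100.0 * counts.tp / visible, fpr=100.0 * counts.fp / visible)


def average_counts(all_counts: Iterable[EvalCounts]) -> EvalCounts:
    """Component-wise arithmetic mean; fractional results are expected."""
    items = list(all_counts)
    if not items:
        raise ValueError("need at least one EvalCounts")
    return EvalCounts(
        tp=float(np.mean([c.tp for c in items])),
        fn=float(np.mean([c.fn for c in items])),
        fp=float(np.mean([c.fp for c in items])),
    )
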