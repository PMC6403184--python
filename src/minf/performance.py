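"""Neurofeedback performance statistics and the cohort median split.

Classified 1-s segments are tallied per condition and converted to three
percentages:

    BaseL = 100 * (C_B + C_MILeft)  / (T_B + T_MILeft)
    BaseR = 100 * (C_B + C_MIRight) / (T_B + T_MIRight)
    LR    = 100 * (C_MILeft + C_MIRight) / (T_MILeft + T_MIRight)

where C_x / T_x are correct and total segment counts for condition x. The
subject-level summary is the maximum of the three (an upper estimate of the
ability to modulate the imagery-related signal), and subjects are split into
low/high performers at the cohort median of that maximum.

By default the baseline counts entering BaseL (resp. BaseR) come from the
baseline segments of left-hand (right-hand) trials only, keeping each
classifier's denominator restricted to segments it ever sees; ``pooled``
baselines are supported as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

CLASSIFIER_PRIORITY = ("BaseL", "BaseR", "LR")


@dataclass
class SegmentCounts:
    """Correct/total classified-segment counts per condition.

    Baseline counts are kept per trial side so that either baseline scope
    ("matching" or "pooled") can be computed from the same tally.
    """

    c_base_left: int = 0
    t_base_left: int = 0
    c_base_right: int = 0
    t_base_right: int = 0
    c_mi_left: int = 0
    t_mi_left: int = 0
    c_mi_right: int = 0
    t_mi_right: int = 0
    side_scope: str = "matching"

    def __post_init__(self) -> None:
        pairs = [
            (self.c_base_left, self.t_base_left), (self.c_base_right, self.t_base_right),
            (self.c_mi_left, self.t_mi_left), (self.c_mi_right, self.t_mi_right),
        ]
        for c, t in pairs:
            if c < 0 or t < 0 or c > t:
                raise ValueError("counts must satisfy 0 <= correct <= total")
        if self.side_scope not in ("matching", "pooled"):
            raise ValueError("side_scope must be 'matching' or 'pooled'")

    def _base(self, side: str) -> tuple[int, int]:
        if self.side_scope == "pooled":
            return (self.c_base_left + self.c_base_right,
                    self.t_base_left + self.t_base_right)
        return ((self.c_base_left, self.t_base_left) if side == "left"
                else (self.c_base_right, self.t_base_right))


@dataclass
class PerformanceResult:
    baseL: float
    baseR: float
    lr: float
    max_perf: float
    best_classifier: str


def classifier_performance(counts: SegmentCounts) -> PerformanceResult:
    """Compute BaseL/BaseR/LR percentages, their maximum and the best classifier.

    Ties between classifiers are broken in the order BaseL, BaseR, LR.
    """
    cbl, tbl = counts._base("left")
    cbr, tbr = counts._base("right")
    if min(tbl + counts.t_mi_left, tbr + counts.t_mi_right,
           counts.t_mi_left + counts.t_mi_right) <= 0:
        raise ValueError("every performance denominator must be positive")
    baseL = 100.0 * (cbl + counts.c_mi_left) / (tbl + counts.t_mi_left)
    baseR = 100.0 * (cbr + counts.c_mi_right) / (tbr + counts.t_mi_right)
    lr = 100.0 * (counts.c_mi_left + counts.c_mi_right) / (
        counts.t_mi_left + counts.t_mi_right)
    vals = {"BaseL": baseL, "BaseR": baseR, "LR": lr}
    best = max(CLASSIFIER_PRIORITY, key=lambda k: vals[k])  # max is stable: first wins ties
    return PerformanceResult(baseL, baseR, lr, vals[best], best)


def max_performance(baseL: float, baseR: float, lr: float) -> PerformanceResult:
    """Assemble a PerformanceResult from the three percentages.

    Useful when the three classifiers were tallied separately (each judges its
    own segment set); ties follow the BaseL, BaseR, LR priority order.
    """
    vals = {"BaseL": baseL, "BaseR": baseR, "LR": lr}
    for v in vals.values():
        if not 0.0 <= v <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    best = max(CLASSIFIER_PRIORITY, key=lambda k: vals[k])
    return PerformanceResult(baseL, baseR, lr, vals[best], best)


def tally_segments(decisions: dict[str, np.ndarray], truths: dict[str, np.ndarray],
                   side_scope: str = "matching") -> SegmentCounts:
    """Tally per-classifier segment decisions into a SegmentCounts.

    ``decisions``/``truths`` map condition keys — "base_left", "base_right"
    (baseline segments from left/right trials, classified by the matching Base
    classifier), "mi_left", "mi_right" — to flat arrays of predicted and true
    labels for each segment.
    """
    c = SegmentCounts(side_scope=side_scope)
    for key in ("base_left", "base_right", "mi_left", "mi_right"):
        if key not in decisions:
            continue
        pred = np.asarray(decisions[key]).ravel()
        true = np.asarray(truths[key]).ravel()
        if pred.shape != true.shape:
            raise ValueError(f"decision/truth shape mismatch for {key}")
        setattr(c, "c_" + key, int((pred == true).sum()))
        setattr(c, "t_" + key, int(pred.size))
    c.__post_init__()  # re-validate after mutation
    return c


def median_split(scores) -> np.ndarray:
    """Label subjects low/high at the sample median (high iff score > median).

    The tie rule (<= median -> low) is deterministic and gives an 11/10 split
    for 21 distinct scores. A constant score vector yields all-low with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("median split needs at least 2 subjects")
    if np.ptp(scores) == 0:
        warnings.warn("all scores identical; every subject labelled 'low'")
        return np.array(["low"] * scores.size)
    med = np.median(scores)
    return np.where(scores > med, "high", "low")
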