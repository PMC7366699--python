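"""Binary-classification metrics for binding-site evaluation.

Per-position predictions are scored against per-position labels with the
standard 2x2 confusion table and the derived statistics SN, SP, PRE, ACC,
MCC, Strength = (SN+SP)/2 and F-measure, plus the rank-based (Mann-Whitney)
AUC.  Any metric whose denominator is zero is reported as 0 and flagged, so
per-target macro-averages stay total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from sklearn.metrics import roc_auc_score

METRIC_NAMES = ("SN", "SP", "PRE", "ACC", "MCC", "Strength", "F")


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise MetricsError("confusion table is empty")


def confusion(pred: set, truth: set, universe: set) -> ConfusionCounts:
    """Confusion counts of a predicted position set against the truth set."""
    pred, truth, universe = set(pred), set(truth), set(universe)
    if not pred <= universe:
        raise MetricsError("predicted positions outside the universe")
    if not truth <= universe:
        raise MetricsError("truth positions outside the universe")
    tp = len(pred & truth)
    fp = len(pred - truth)
    fn = len(truth - pred)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, flags: set, name: str) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def evaluate(c: ConfusionCounts) -> dict:
    """SN, SP, PRE, ACC, MCC, Strength and F-measure from a confusion table.

    Returns the metric dict plus ``zero_denominator_flags``, the set of
    metrics that were reported as 0 because their denominator vanished.
    """
    flags: set = set()
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sn = _ratio(tp, tp + fn, flags, "SN")
    sp = _ratio(tn, tn + fp, flags, "SP")
    pre = _ratio(tp, tp + fp, flags, "PRE")
    acc = _ratio(tp + tn, tp + tn + fp + fn, flags, "ACC")
    mcc_den = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, flags, "MCC")
    strength = (sn + sp) / 2
    f = _ratio(2 * pre * sn, pre + sn, flags, "F")
    return {
        "SN": sn, "SP": sp, "PRE": pre, "ACC": acc, "MCC": mcc,
        "Strength": strength, "F": f, "zero_denominator_flags": flags,
    }


def auc(scored_positions) -> float | None:
    """Rank-based AUC with midrank tie handling; None when one class is absent."""
    scores = [float(s) for s, _ in scored_positions]
    labels = [int(bool(t)) for _, t in scored_positions]
    if len(set(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def macro_average(per_target_metrics) -> dict:
    """Mean of each metric over targets (macro-average)."""
    out = {}
    for name in METRIC_NAMES:
        values = [m[name] for m in per_target_metrics]
        out[name] = sum(values) / len(values) if values else 0.0
    return out
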