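"""Binary-classifier bookkeeping: confusion metrics, the informative-tilt
rule, and pooling of IH33 features with externally supplied feature columns.

Conventions: in each binary problem the first-named class is the positive
class (Control in Control-vs-AD, AD in AD-vs-AD-CVD, AD-CVD in
AD-CVD-vs-Control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

#: The three binary problems as (positive, negative) class pairs.
PROBLEMS: dict[str, tuple[str, str]] = {
    "Control-vs-AD": ("Control", "AD"),
    "AD-vs-AD-CVD": ("AD", "AD-CVD"),
    "AD-CVD-vs-Control": ("AD-CVD", "Control"),
}

INFORMATIVE_THRESHOLD_PCT = 75.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if c.total == 0:
        raise ValueError("cannot compute accuracy of zero counts")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when there are no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else math.nan


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when there are no negatives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else math.nan


@dataclass(frozen=True)
class BinaryPerf:
    """Fold-averaged performance of one binary classifier (fractions)."""

    problem: str
    tilt: str  # a tilt name or "pooled"
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    n_folds: int

    def weight_for(self, cls: str) -> float:
        """Training-averaged recall of ``cls`` in this problem: sensitivity
        when ``cls`` is the positive class, specificity when negative."""
        pos, neg = PROBLEMS[self.problem]
        if cls == pos:
            return self.sensitivity
        if cls == neg:
            return self.specificity
        raise KeyError(f"{cls} is not part of problem {self.problem}")


def informative_tilts(
    per_tilt: Mapping[str, BinaryPerf] | Mapping[str, float],
    threshold_pct: float = INFORMATIVE_THRESHOLD_PCT,
) -> list[str]:
    """Tilts whose averaged test accuracy is >= threshold, sorted descending
    by accuracy (stable for ties)."""
    acc = {
        tilt: (p.accuracy * 100 if isinstance(p, BinaryPerf) else float(p))
        for tilt, p in per_tilt.items()
    }
    keep = [t for t in acc if acc[t] >= threshold_pct]
    return sorted(keep, key=lambda t: -acc[t])


def pool_features(ih33_fm, external_fm):
    """Column-wise join of an IH33 feature matrix with externally supplied
    feature columns (e.g. averaged-FP waveform features from a prior
    analysis) over the same subject universe.

    Subjects present in only one matrix are kept with missing cells;
    duplicate feature keys raise.
    """
    from .selection import FeatureMatrix  # local import to avoid a cycle

    if external_fm is None or external_fm.values.shape[1] == 0:
        return ih33_fm
    dup = set(ih33_fm.values.columns) & set(external_fm.values.columns)
    if dup:
        raise ValueError(f"duplicate feature keys: {sorted(dup)}")
    joined = ih33_fm.values.join(external_fm.values, how="outer")
    labels = ih33_fm.labels.combine_first(external_fm.labels).reindex(joined.index)
    feature_defs = {**ih33_fm.feature_defs, **external_fm.feature_defs}
    return FeatureMatrix(
        values=joined,
        labels=labels,
        positive=ih33_fm.positive,
        negative=ih33_fm.negative,
        feature_defs=feature_defs,
    )
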