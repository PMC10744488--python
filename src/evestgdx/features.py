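"""Discovery of region-difference features in averaged IH33 signals.

A candidate feature is found when the standard-error bands around the two
groups' mean histograms separate mutually on both sides of the crossing of
the mean curves: the group shifted toward longer intervals has more mass in
a high-interval region and less in a low-interval region. The feature value
for a subject is the mean of the bins in the high region minus the mean of
the bins in the low region -- a signed index of shift toward longer
intervals.

Feature discovery is repeated over many resampled training sets (leaving
20% of each group out) so that only features stable under resampling
survive to the selection stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ih33 import IH33Signal, SignalKey

ALPHA = 0.05
#: The first/last two bins and the three bins at the pooled-mean peak are
#: never part of a feature region (noise-prone tails and peak).
EDGE_EXCLUSION = 2
PEAK_EXCLUSION_HALFWIDTH = 1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TrainingSet:
    """One resampled partition: per-population retained / held-out ids."""

    index: int
    retained: tuple[tuple[str, tuple[str, ...]], ...]
    held_out: tuple[tuple[str, tuple[str, ...]], ...]

    def retained_ids(self, population: str) -> tuple[str, ...]:
        return dict(self.retained)[population]

    def held_out_ids(self, population: str) -> tuple[str, ...]:
        return dict(self.held_out)[population]


@dataclass(frozen=True, order=True)
class FeatureDef:
    """A signal key plus two disjoint bin regions; the feature value is
    mean(region_high) - mean(region_low)."""

    key: SignalKey
    region_low: tuple[int, ...]
    region_high: tuple[int, ...]
    orientation: str = ""  # label of the group with the longer-interval shift

    def __post_init__(self) -> None:
        if not self.region_low or not self.region_high:
            raise ValueError("regions must be non-empty")
        if max(self.region_low) >= min(self.region_high):
            raise ValueError("region_low must lie entirely below region_high")

    def identity(self) -> tuple[SignalKey, str]:
        """Consensus identity: features found in different training sets are
        the 'same' feature when signal key and orientation agree."""
        return (self.key, self.orientation)


@dataclass(frozen=True)
class CandidateFeature:
    feature: FeatureDef
    p_value: float
    test_used: str  # "t" | "wilcoxon"
    set_index: int = -1

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


# ---------------------------------------------------------------------------
# training-set resampling


def make_training_sets(
    labels: Mapping[str, str],
    n_sets: int = 1600,
    holdout: float = 0.2,
    seed: int = 0,
) -> list[TrainingSet]:
    """Random per-population 80/20 partitions of the training cohort.

    Every subject is guaranteed to appear in at least one hold-out across
    the collection (deficits are repaired by swapping into an existing
    hold-out); a warning is raised if ``n_sets`` is too small to repair.
    """
    rng = np.random.default_rng(seed)
    pops: dict[str, list[str]] = {}
    for sid, lab in labels.items():
        pops.setdefault(lab, []).append(sid)
    for lab, ids in pops.items():
        if len(ids) < 5:
            raise ValueError(
                f"population {lab!r} has {len(ids)} members; need >= 5 so that "
                "a 20% hold-out contains at least one subject"
            )
        ids.sort()

    holdouts: dict[str, list[list[str]]] = {lab: [] for lab in pops}
    for lab, ids in pops.items():
        k = max(1, round(holdout * len(ids)))
        for _ in range(n_sets):
            held = list(rng.choice(ids, size=k, replace=False))
            holdouts[lab].append(held)

    # coverage repair: swap never-held-out subjects into some hold-out
    for lab, ids in pops.items():
        counts = {sid: 0 for sid in ids}
        for held in holdouts[lab]:
            for sid in held:
                counts[sid] += 1
        for sid in ids:
            if counts[sid] > 0:
                continue
            donors = [
                (si, j)
                for si in range(n_sets)
                for j, other in enumerate(holdouts[lab][si])
                if counts[other] > 1
            ]
            if not donors:
                warnings.warn(
                    f"subject {sid} never held out and no swap possible; "
                    "increase n_sets",
                    stacklevel=2,
                )
                continue
            si, j = donors[rng.integers(len(donors))]
            counts[holdouts[lab][si][j]] -= 1
            holdouts[lab][si][j] = sid
            counts[sid] += 1

    sets = []
    for i in range(n_sets):
        held = {lab: tuple(sorted(holdouts[lab][i])) for lab in pops}
        retained = {
            lab: tuple(s for s in pops[lab] if s not in set(held[lab]))
            for lab in pops
        }
        sets.append(
            TrainingSet(
                index=i,
                retained=tuple(sorted(retained.items())),
                held_out=tuple(sorted(held.items())),
            )
        )
    return sets


# ---------------------------------------------------------------------------
# band-separation search


def forbidden_bins(mean_a: np.ndarray, mean_b: np.ndarray) -> set[int]:
    """Bins excluded from feature regions: the two bins at each end of the
    grid and the three bins at the peak of the pooled mean curve."""
    n = mean_a.size
    pooled_peak = int(np.argmax((mean_a + mean_b) / 2))
    bad = set(range(EDGE_EXCLUSION)) | set(range(n - EDGE_EXCLUSION, n))
    bad |= {
        k
        for k in range(
            pooled_peak - PEAK_EXCLUSION_HALFWIDTH,
            pooled_peak + PEAK_EXCLUSION_HALFWIDTH + 1,
        )
        if 0 <= k < n
    }
    return bad


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def find_separation_regions(
    group_a: Sequence[IH33Signal],
    group_b: Sequence[IH33Signal],
    labels: tuple[str, str] = ("A", "B"),
    require_both_sides: bool = True,
) -> FeatureDef | None:
    """Search for mutual standard-error-band separation between two groups.

    Per bin, the groups separate when one group's lower band (mean - SE)
    exceeds the other's upper band (mean + SE), with SE = SD/sqrt(n). A
    feature is emitted when separating bins exist on both sides of a
    crossing of the two mean curves; the regions are the maximal contiguous
    separating runs adjacent to that crossing. With multiple crossings the
    one flanked by the largest total separating run length wins.

    Returns ``None`` when no mutual separation exists (including the
    identical-groups case). ``require_both_sides=False`` relaxes crossing
    adjacency and pairs the largest separating runs on each side.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 signals")
    keys = {s.key for s in group_a} | {s.key for s in group_b}
    if len(keys) != 1:
        raise ValueError(f"signals mix keys: {keys}")
    key = next(iter(keys))

    a = np.vstack([s.values for s in group_a])
    b = np.vstack([s.values for s in group_b])
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    se_a = a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])
    se_b = b.std(axis=0, ddof=1) / np.sqrt(b.shape[0])

    sep = (mean_a - se_a > mean_b + se_b) | (mean_b - se_b > mean_a + se_a)
    for k in forbidden_bins(mean_a, mean_b):
        sep[k] = False
    runs = _contiguous_runs(sep)
    if not runs:
        return None

    diff = mean_a - mean_b
    sign = np.sign(diff)
    crossings = [i for i in range(len(diff) - 1) if sign[i] * sign[i + 1] < 0]

    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    for c in crossings:
        low_candidates = [r for r in runs if r[1] <= c]
        high_candidates = [r for r in runs if r[0] >= c + 1]
        if not low_candidates or not high_candidates:
            continue
        low = max(low_candidates, key=lambda r: r[1])  # adjacent below crossing
        high = min(high_candidates, key=lambda r: r[0])  # adjacent above
        size = (low[1] - low[0] + 1) + (high[1] - high[0] + 1)
        if best is None or size > best[0]:
            best = (size, low, high)

    if best is None and not require_both_sides and crossings:
        c = crossings[0]
        lows = [r for r in runs if r[1] <= c]
        highs = [r for r in runs if r[0] >= c + 1]
        if lows and highs:
            low = max(lows, key=lambda r: r[1] - r[0])
            high = max(highs, key=lambda r: r[1] - r[0])
            best = ((low[1] - low[0] + 1) + (high[1] - high[0] + 1), low, high)
    if best is None:
        return None

    _, low, high = best
    region_low = tuple(range(low[0], low[1] + 1))
    region_high = tuple(range(high[0], high[1] + 1))
    # orientation: the group with more mass in the high region is the one
    # shifted toward longer intervals
    a_high = mean_a[list(region_high)].mean() - mean_a[list(region_low)].mean()
    b_high = mean_b[list(region_high)].mean() - mean_b[list(region_low)].mean()
    orientation = labels[0] if a_high > b_high else labels[1]
    return FeatureDef(key, region_low, region_high, orientation)


# ---------------------------------------------------------------------------
# feature value and significance test


def compute_feature(signal: IH33Signal | None, feature: FeatureDef) -> float | None:
    """Mean of the high-interval region minus mean of the low-interval region.

    Returns ``None`` when the subject lacks the signal.
    """
    if signal is None:
        return None
    if signal.key != feature.key:
        raise ValueError(f"signal key {signal.key} does not match feature {feature.key}")
    n = signal.values.size
    if max(feature.region_high) >= n or min(feature.region_low) < 0:
        raise ValueError("feature regions fall outside the grid")
    high = signal.values[list(feature.region_high)].mean()
    low = signal.values[list(feature.region_low)].mean()
    return float(high - low)


def test_feature(
    values_a: Sequence[float], values_b: Sequence[float], alpha_normality: float = ALPHA
) -> tuple[float, str]:
    """Two-sided two-group test, Shapiro-Wilk gated.

    Both groups normal at ``alpha_normality`` -> unpaired t-test; otherwise
    Wilcoxon-Mann-Whitney. Missing values are dropped per group. Identical
    constant samples give p = 1 by convention.
    """
    a = np.asarray([v for v in values_a if v is not None and np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in values_b if v is not None and np.isfinite(v)], dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 non-missing values per group")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > alpha_normality

    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0, "t"
    if _normal(a) and _normal(b):
        return float(stats.ttest_ind(a, b).pvalue), "t"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "wilcoxon"
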