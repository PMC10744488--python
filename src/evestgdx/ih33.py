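"""Interval-histogram (IH33) construction and quality control.

An IH33 signal is the normalized histogram of the time intervals spanned by
every 33rd detected field potential (FP) in a 1.5 s recording segment --
roughly 100 ms intervals, probing ~10 Hz modulation of the FP firing
pattern. Histograms are built on a fixed 25-bin logarithmic grid and are
unit-sum.

Segments pass a three-rule quality control before histogramming:

(i)   the FP occurrence-time curve versus FP index must be close to linear
      (a "stepwise" curve indicates dropouts or artifacts);
(ii)  at least 350 FPs must be registered and their occurrence times must
      span at least 97% of the segment duration;
(iii) the resulting histogram must be unimodal -- a secondary mode holding
      more than 10% of the mass rejects the segment.

Rules are checked in that order and the first failure is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .grid import BinGrid, DEFAULT_GRID

# ---------------------------------------------------------------------------
# vocabulary

UPRIGHT_TILTS = ("up/down", "rotation", "back/forward", "IT", "CT")
SUPINE_TILTS = ("supine up/down", "supine rotation")
TILTS = UPRIGHT_TILTS + SUPINE_TILTS

PHASES = ("BGi", "OnAA", "OnBB", "RTC_BGi", "RTC_OnAA", "RTC_OnBB")
BACKGROUND_PHASES = ("BGi", "RTC_BGi")

EARS = ("L", "R")

UPRIGHT_AVERAGE = "Upright average"
SUPINE_AVERAGE = "Supine average"

#: Background segments entering the posture averages. The upright sitting
#: posture contributes 7 background segments and the supine posture 4; the
#: exact composition is configurable (see ``derive_signals``). Default: BGi
#: of all five upright tilts plus the return-to-center backgrounds of the
#: two translation tilts.
DEFAULT_UPRIGHT_COMPOSITION = (
    ("up/down", "BGi"),
    ("rotation", "BGi"),
    ("back/forward", "BGi"),
    ("IT", "BGi"),
    ("CT", "BGi"),
    ("up/down", "RTC_BGi"),
    ("back/forward", "RTC_BGi"),
)
DEFAULT_SUPINE_COMPOSITION = (
    ("supine up/down", "BGi"),
    ("supine up/down", "RTC_BGi"),
    ("supine rotation", "BGi"),
    ("supine rotation", "RTC_BGi"),
)

SEGMENT_DURATION_MS = 1500.0
DEFAULT_LAG = 33


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class SignalKey:
    """Identifies one IH33 signal: tilt (or posture average), phase, side."""

    tilt: str
    phase: str
    side: str  # L, R, LR (sum) or L-R (asymmetry)

    def __str__(self) -> str:
        return f"{self.tilt}|{self.phase}|{self.side}"

    @classmethod
    def parse(cls, s: str) -> "SignalKey":
        tilt, phase, side = s.split("|")
        return cls(tilt, phase, side)


@dataclass(frozen=True)
class FPSegment:
    """One ear's detected FP occurrence times for one 1.5 s tilt phase."""

    subject_id: str
    tilt: str
    phase: str
    ear: str
    fp_times: np.ndarray  # ms, strictly ascending, within [0, duration]

    def __post_init__(self) -> None:
        t = np.asarray(self.fp_times, dtype=float)
        object.__setattr__(self, "fp_times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("fp_times must be strictly ascending and non-negative")


@dataclass(frozen=True)
class IH33Signal:
    """A 25-bin interval histogram (or derived combination) for one key."""

    key: SignalKey
    values: np.ndarray
    normalized: bool = True
    n_averaged: int = 1  # divisor used when the signal is a posture average

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.normalized:
            if v.min() < 0 or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"normalized signal must be non-negative unit-sum ({self.key})")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str = "none"  # nonsmooth_occurrence | too_few_fps | short_span | bimodal

    def __post_init__(self) -> None:
        if self.passed != (self.reason == "none"):
            raise ValueError("pass flag inconsistent with reason")


# ---------------------------------------------------------------------------
# histogram construction


def build_ih33(
    segment: FPSegment,
    grid: BinGrid = DEFAULT_GRID,
    lag: int = DEFAULT_LAG,
) -> IH33Signal:
    """Histogram of sliding lag-33 interval differences, normalized to unit sum.

    Intervals are ``t[i+lag] - t[i]`` for every valid ``i`` (overlapping
    windows). Intervals outside the grid range are clipped into the end
    bins so total mass is preserved.

    Raises ``ValueError`` if the segment has fewer than ``lag + 1`` FPs;
    quality control is a separate concern (see :func:`qc_segment`).
    """
    t = segment.fp_times
    if t.size < lag + 1:
        raise ValueError(
            f"need at least {lag + 1} FPs to form lag-{lag} intervals, got {t.size}"
        )
    intervals = t[lag:] - t[:-lag]
    counts = np.bincount(grid.assign(intervals), minlength=grid.n_bins).astype(float)
    return IH33Signal(
        key=SignalKey(segment.tilt, segment.phase, segment.ear),
        values=counts / counts.sum(),
    )


# ---------------------------------------------------------------------------
# quality control


def _is_nonsmooth(
    t: np.ndarray, duration_ms: float, resid_frac: float, gap_factor: float
) -> bool:
    """Occurrence-time curve vs FP index deviates from a semi-linear curve."""
    idx = np.arange(t.size)
    coef = np.polyfit(idx, t, 1)
    resid = t - np.polyval(coef, idx)
    if np.max(np.abs(resid)) > resid_frac * duration_ms:
        return True
    gaps = np.diff(t)
    if gaps.size and np.max(gaps) > gap_factor * np.median(gaps):
        return True
    return False


def secondary_mode_mass(values: np.ndarray, smooth_width: int = 3) -> float:
    """Mass fraction on the smaller side of the deepest trough between the
    two largest modes of the histogram (0 if the histogram is unimodal).

    Modes are located on a moving-average smoothed copy of the curve; the
    mass split is computed on the raw values.
    """
    v = np.asarray(values, dtype=float)
    s = uniform_filter1d(v, size=smooth_width, mode="nearest")
    peaks = [
        i
        for i in range(s.size)
        if (i == 0 or s[i] > s[i - 1]) and (i == s.size - 1 or s[i] >= s[i + 1])
    ]
    peaks = [i for i in peaks if s[i] > 0]
    if len(peaks) < 2:
        return 0.0
    # two largest modes by smoothed height
    p1, p2 = sorted(sorted(peaks, key=lambda i: s[i], reverse=True)[:2])
    if p1 == p2:
        return 0.0
    trough = p1 + 1 + int(np.argmin(s[p1 + 1 : p2 + 1]))
    total = v.sum()
    if total <= 0:
        return 0.0
    left = v[:trough].sum() / total
    return min(left, 1.0 - left)


def qc_segment(
    segment: FPSegment,
    duration_ms: float = SEGMENT_DURATION_MS,
    grid: BinGrid = DEFAULT_GRID,
    lag: int = DEFAULT_LAG,
    min_fps: int = 350,
    min_span_frac: float = 0.97,
    smooth_resid_frac: float = 0.10,
    smooth_gap_factor: float = 20.0,
    max_secondary_mode: float = 0.10,
) -> QCResult:
    """Apply the three exclusion rules in order; report the first failure."""
    t = segment.fp_times
    if t.size < 2:
        return QCResult(False, "too_few_fps")
    if _is_nonsmooth(t, duration_ms, smooth_resid_frac, smooth_gap_factor):
        return QCResult(False, "nonsmooth_occurrence")
    if t.size < min_fps:
        return QCResult(False, "too_few_fps")
    if (t[-1] - t[0]) < min_span_frac * duration_ms:
        return QCResult(False, "short_span")
    if t.size >= lag + 1:
        hist = build_ih33(segment, grid, lag)
        if secondary_mode_mass(hist.values) > max_secondary_mode:
            return QCResult(False, "bimodal")
    return QCResult(True)


# ---------------------------------------------------------------------------
# derived signals


def _mean_signal(
    signals: Sequence[IH33Signal], key: SignalKey
) -> IH33Signal | None:
    if not signals:
        return None
    stacked = np.vstack([s.values for s in signals])
    return IH33Signal(key, stacked.mean(axis=0), normalized=True, n_averaged=len(signals))


def derive_signals(
    per_segment: Mapping[SignalKey, IH33Signal],
    upright_composition: Iterable[tuple[str, str]] = DEFAULT_UPRIGHT_COMPOSITION,
    supine_composition: Iterable[tuple[str, str]] = DEFAULT_SUPINE_COMPOSITION,
) -> dict[SignalKey, IH33Signal]:
    """Augment per-segment signals with posture averages and ear combinations.

    Emits, for one subject:

    * ``Upright average`` / ``Supine average`` per ear -- mean of the
      available background-segment signals of that posture (missing
      segments are skipped; the divisor actually used is recorded);
    * ``LR`` (bin-wise sum renormalized to unit sum) and ``L-R`` (bin-wise
      difference, signed, not renormalized) for every background signal,
      including the posture averages.

    An average with zero available segments is omitted, not emitted as zero.
    """
    out: dict[SignalKey, IH33Signal] = dict(per_segment)

    for posture, comp in (
        (UPRIGHT_AVERAGE, tuple(upright_composition)),
        (SUPINE_AVERAGE, tuple(supine_composition)),
    ):
        for ear in EARS:
            present = [
                per_segment[SignalKey(t, p, ear)]
                for t, p in comp
                if SignalKey(t, p, ear) in per_segment
            ]
            avg = _mean_signal(present, SignalKey(posture, "BGi", ear))
            if avg is not None:
                out[avg.key] = avg

    # ear combinations for background signals (per tilt and posture averages)
    combo_bases = [
        (tilt, phase) for tilt in TILTS for phase in BACKGROUND_PHASES
    ] + [(UPRIGHT_AVERAGE, "BGi"), (SUPINE_AVERAGE, "BGi")]
    for tilt, phase in combo_bases:
        left = out.get(SignalKey(tilt, phase, "L"))
        right = out.get(SignalKey(tilt, phase, "R"))
        if left is None or right is None:
            continue
        total = left.values + right.values
        out[SignalKey(tilt, phase, "LR")] = IH33Signal(
            SignalKey(tilt, phase, "LR"), total / total.sum(), normalized=True
        )
        out[SignalKey(tilt, phase, "L-R")] = IH33Signal(
            SignalKey(tilt, phase, "L-R"), left.values - right.values, normalized=False
        )
    return out


def signals_for_tilt(tilt: str) -> list[SignalKey]:
    """All signal keys analyzed for one tilt: the six segments per ear, ear
    combinations of the background segments, and the posture average of the
    tilt's posture (with its combinations)."""
    keys = [SignalKey(tilt, phase, ear) for phase in PHASES for ear in EARS]
    keys += [
        SignalKey(tilt, phase, side)
        for phase in BACKGROUND_PHASES
        for side in ("LR", "L-R")
    ]
    posture = SUPINE_AVERAGE if tilt in SUPINE_TILTS else UPRIGHT_AVERAGE
    keys += [SignalKey(posture, "BGi", side) for side in ("L", "R", "LR", "L-R")]
    return keys
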