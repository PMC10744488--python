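"""Synthetic cohort generation.

Real electrovestibulography recordings for the three study groups (healthy
controls, Alzheimer's disease, and AD mixed with cerebrovascular disease)
are not publicly deposited, so this module generates labeled cohorts with
the statistical structure the downstream analysis assumes:

* inter-FP gaps are gamma distributed (positive support, tunable
  coefficient of variation), so the lag-33 interval histograms are unimodal
  and approximately log-normal on the logarithmic bin grid;
* the class effect is a signed shift of the mean lag-33 interval -- AD
  shifted toward longer intervals (lower firing frequencies), AD-CVD toward
  shorter intervals, controls in between;
* MoCA, age and sex are drawn from class-specific distributions; age and
  sex carry no planted effect on the signals;
* a configurable fraction of segments is missing at random, emulating
  artifact-driven exclusions.

Two paths are provided: :func:`generate_cohort` simulates FP occurrence
times (exercising the histogram builder and QC), while
:func:`generate_ih33_cohort` emits 25-bin histograms directly via
multinomial sampling around a class-shifted log-normal mode -- a much
faster fixture path for selection/classification tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import BinGrid, DEFAULT_GRID
from .ih33 import (
    EARS,
    PHASES,
    SEGMENT_DURATION_MS,
    TILTS,
    FPSegment,
    IH33Signal,
    SignalKey,
    derive_signals,
)

LABELS = ("Control", "AD", "AD-CVD")

#: Per-class MoCA mean/SD (training-cohort demographics).
DEFAULT_MOCA_PARAMS = {
    "Control": (27.6, 1.7),
    "AD": (16.4, 4.8),
    "AD-CVD": (17.0, 4.4),
}
DEFAULT_AGE_PARAMS = {
    "Control": (65.3, 7.0),
    "AD": (72.5, 7.5),
    "AD-CVD": (75.8, 7.3),
}
DEFAULT_MALE_FRACTION = {
    "Control": 9 / 24,
    "AD": 11 / 16,
    "AD-CVD": 9 / 13,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``shift_ad`` / ``shift_adcvd`` are the signed shifts of the mean lag-33
    interval (ms) relative to control; ``within_class_sd`` is the
    between-subject SD of that mean within a class. ``base_mean_interval``
    is the control-class mean lag-33 interval (~100 ms, i.e. 33 gaps of
    ``mean_fp_gap`` ~ 3.3 ms each).
    """

    n_control: int = 24
    n_ad: int = 16
    n_adcvd: int = 13
    shift_ad: float = 10.0
    shift_adcvd: float = -10.0
    within_class_sd: float = 6.0
    base_mean_interval: float = 108.9
    mean_fp_gap: float = 3.3
    segment_duration: float = SEGMENT_DURATION_MS
    missing_rate: float = 0.05
    gap_cv: float = 0.6  # coefficient of variation of the gamma gaps
    ih33_log_sd: float = 0.25  # log-scale width of directly emitted histograms
    ih33_n_intervals: int = 422  # multinomial draws per emitted histogram
    moca_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOCA_PARAMS)
    )
    age_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PARAMS)
    )
    male_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MALE_FRACTION)
    )
    #: Restrict the class shift to these (tilt, phase) segments; ``None``
    #: applies the shift to every segment (a class-wide physiology).
    shift_segments: tuple[tuple[str, str], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_ad, self.n_adcvd) < 1:
            raise ValueError("all class counts must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.segment_duration <= 0:
            raise ValueError("segment_duration must be positive")
        for shift in (self.shift_ad, self.shift_adcvd, 0.0):
            if self.base_mean_interval + shift <= 0:
                raise ValueError("class shift yields a non-positive mean interval")
        if abs(self.base_mean_interval - 33 * self.mean_fp_gap) > 0.1 * self.base_mean_interval:
            warnings.warn(
                "base_mean_interval is not ~33 x mean_fp_gap; histograms may "
                "sit off-grid",
                stacklevel=2,
            )

    def class_shift(self, label: str) -> float:
        return {"Control": 0.0, "AD": self.shift_ad, "AD-CVD": self.shift_adcvd}[label]

    def class_sizes(self) -> dict[str, int]:
        return {"Control": self.n_control, "AD": self.n_ad, "AD-CVD": self.n_adcvd}


@dataclass
class SyntheticSubject:
    subject_id: str
    true_label: str
    moca: int
    age: float
    sex: str
    segments: dict[tuple[str, str, str], FPSegment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.moca <= 30):
            raise ValueError("MoCA must be within [0, 30]")


def _draw_demographics(
    config: CohortConfig, label: str, rng: np.random.Generator
) -> tuple[int, float, str]:
    m_mu, m_sd = config.moca_params[label]
    moca = int(np.clip(round(rng.normal(m_mu, m_sd)), 0, 30))
    a_mu, a_sd = config.age_params[label]
    age = float(rng.normal(a_mu, a_sd))
    sex = "M" if rng.random() < config.male_fraction[label] else "F"
    return moca, age, sex


def _segment_shift_applies(config: CohortConfig, tilt: str, phase: str) -> bool:
    return config.shift_segments is None or (tilt, phase) in config.shift_segments


def _simulate_fp_times(
    mean_interval: float, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-gap FP train over one segment; returns strictly ascending times."""
    gap_mean = mean_interval / 33.0
    shape = 1.0 / config.gap_cv**2
    scale = gap_mean * config.gap_cv**2
    n_draw = int(math.ceil(config.segment_duration / gap_mean * 1.3)) + 10
    gaps = rng.gamma(shape, scale, size=n_draw)
    times = np.cumsum(gaps)
    return times[times < config.segment_duration]


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Simulate FP-time-level subjects; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    subjects: list[SyntheticSubject] = []
    for label in LABELS:
        for i in range(config.class_sizes()[label]):
            moca, age, sex = _draw_demographics(config, label, rng)
            subj = SyntheticSubject(
                subject_id=f"{label}-{i:03d}",
                true_label=label,
                moca=moca,
                age=age,
                sex=sex,
            )
            subject_offset = rng.normal(0.0, config.within_class_sd)
            for tilt in TILTS:
                for phase in PHASES:
                    for ear in EARS:
                        if rng.random() < config.missing_rate:
                            continue
                        mean_interval = config.base_mean_interval + subject_offset
                        if _segment_shift_applies(config, tilt, phase):
                            mean_interval += config.class_shift(label)
                        if mean_interval <= 0:
                            raise ValueError("subject mean interval became non-positive")
                        times = _simulate_fp_times(mean_interval, config, rng)
                        subj.segments[(tilt, phase, ear)] = FPSegment(
                            subj.subject_id, tilt, phase, ear, times
                        )
            subjects.append(subj)
    return subjects


def _ih33_curve(
    mode_interval: float, grid: BinGrid, log_sd: float
) -> np.ndarray:
    w = np.exp(-((np.log(grid.centers) - np.log(mode_interval)) ** 2) / (2 * log_sd**2))
    return w / w.sum()


def generate_ih33_cohort(
    config: CohortConfig, grid: BinGrid = DEFAULT_GRID
) -> list[tuple[SyntheticSubject, dict[SignalKey, IH33Signal]]]:
    """Emit unit-sum 25-bin histograms directly, bypassing FP simulation.

    Each present (tilt, phase, ear) signal is a multinomial draw of
    ``ih33_n_intervals`` counts around a discretized log-normal curve whose
    mode is the subject's (class-shifted) mean interval. Ear combinations
    and posture averages are derived exactly as for real data.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for label in LABELS:
        for i in range(config.class_sizes()[label]):
            moca, age, sex = _draw_demographics(config, label, rng)
            subj = SyntheticSubject(
                subject_id=f"{label}-{i:03d}",
                true_label=label,
                moca=moca,
                age=age,
                sex=sex,
            )
            subject_offset = rng.normal(0.0, config.within_class_sd)
            per_segment: dict[SignalKey, IH33Signal] = {}
            for tilt in TILTS:
                for phase in PHASES:
                    for ear in EARS:
                        if rng.random() < config.missing_rate:
                            continue
                        mode = config.base_mean_interval + subject_offset
                        if _segment_shift_applies(config, tilt, phase):
                            mode += config.class_shift(label)
                        curve = _ih33_curve(mode, grid, config.ih33_log_sd)
                        counts = rng.multinomial(config.ih33_n_intervals, curve)
                        key = SignalKey(tilt, phase, ear)
                        per_segment[key] = IH33Signal(
                            key, counts / counts.sum(), normalized=True
                        )
            out.append((subj, derive_signals(per_segment)))
    return out


# ---------------------------------------------------------------------------
# round-trip IO


def cohort_metadata(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "label": [s.true_label for s in subjects],
            "moca": [s.moca for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
        }
    )


def segments_long_table(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for (tilt, phase, ear), seg in s.segments.items():
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "tilt": tilt,
                        "phase": phase,
                        "ear": ear,
                        "fp_time_ms": seg.fp_times,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "tilt", "phase", "ear", "fp_time_ms"]
        )
    return pd.concat(rows, ignore_index=True)


def write_cohort(
    subjects: Sequence[SyntheticSubject], metadata_path: str, segments_path: str
) -> None:
    cohort_metadata(subjects).to_csv(metadata_path, index=False)
    segments_long_table(subjects).to_csv(segments_path, index=False)


def read_cohort(metadata_path: str, segments_path: str) -> list[SyntheticSubject]:
    meta = pd.read_csv(metadata_path)
    seg = pd.read_csv(segments_path)
    subjects = []
    grouped = dict(tuple(seg.groupby("subject_id"))) if len(seg) else {}
    for _, row in meta.iterrows():
        subj = SyntheticSubject(
            subject_id=row["subject_id"],
            true_label=row["label"],
            moca=int(row["moca"]),
            age=float(row["age"]),
            sex=row["sex"],
        )
        sub_seg = grouped.get(row["subject_id"])
        if sub_seg is not None:
            for (tilt, phase, ear), g in sub_seg.groupby(
                ["tilt", "phase", "ear"], sort=False
            ):
                subj.segments[(tilt, phase, ear)] = FPSegment(
                    subj.subject_id,
                    tilt,
                    phase,
                    ear,
                    np.sort(g["fp_time_ms"].to_numpy()),
                )
        subjects.append(subj)
    return subjects
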