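import numpy as np
import pytest

from evestgdx.ih33 import FPSegment
from evestgdx.synthetic import CohortConfig, generate_ih33_cohort

#: two-bin shift of the mode on the default geometric grid (ms)
TWO_BIN_SHIFT = 108.9 * (1.0823**2 - 1)

NULL_MOCA = {"Control": (27.6, 1.7), "AD": (27.6, 1.7), "AD-CVD": (27.6, 1.7)}


def even_segment(n_fps: int, span_ms: float = 1500.0, tilt: str = "up/down",
                 phase: str = "BGi", ear: str = "L") -> FPSegment:
    """n evenly spaced FPs with the first at 0 and the last just below span."""
    times = np.arange(n_fps) * (span_ms / n_fps)
    return FPSegment("subj", tilt, phase, ear, times)


def two_regime_segment(fast_gap: float = 1.5, slow_gap: float = 3.3,
                       fast_start: float = 1370.0, dur: float = 1500.0) -> FPSegment:
    """FP train with a late block of faster firing -> bimodal histogram."""
    times = [0.0]
    t = 0.0
    while True:
        t += fast_gap if t >= fast_start else slow_gap
        if t >= dur:
            break
        times.append(t)
    return FPSegment("subj", "up/down", "BGi", "L", np.array(times))


@pytest.fixture(scope="session")
def planted_cohort():
    """3 x 20 subjects, two-bin class shift planted only in the supine
    up/down OnBB segments; histogram-level generation."""
    cfg = CohortConfig(
        n_control=20, n_ad=20, n_adcvd=20,
        shift_ad=TWO_BIN_SHIFT, shift_adcvd=-TWO_BIN_SHIFT,
        shift_segments=(("supine up/down", "OnBB"),),
        seed=11,
    )
    pairs = generate_ih33_cohort(cfg)
    signals = {s.subject_id: sigs for s, sigs in pairs}
    labels = {s.subject_id: s.true_label for s, _ in pairs}
    moca = {s.subject_id: s.moca for s, _ in pairs}
    return signals, labels, moca
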