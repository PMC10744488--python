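"""Logarithmic bin grid for interval histograms.

The IH33 histogram lives on 25 logarithmically spaced bins covering the
inter-event interval range around the ~100 ms lag-33 interval (roughly
31-208 ms, i.e. ~5-32 Hz when read as frequency = 1/time). Bin *centers*
form a geometric sequence; edges are the geometric midpoints between
consecutive centers, with the outer edges extrapolated at the same ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default geometric grid: centers c_k = 31.2 * 1.0823**k, k = 0..24.
#: This places the canonical feature-bin midpoints (68.9, 74.5, 80.6, 87.3,
#: 94.5, 129.6, 140.2, 151.8, 164.3 ms) at integer k between 10 and 21.
DEFAULT_FIRST_CENTER_MS = 31.2
DEFAULT_RATIO = 1.0823
N_BINS = 25


@dataclass(frozen=True)
class BinGrid:
    """25 log-spaced bin centers (ms) with implied geometric edges."""

    first_center_ms: float = DEFAULT_FIRST_CENTER_MS
    ratio: float = DEFAULT_RATIO
    n_bins: int = N_BINS
    centers: np.ndarray = field(init=False, repr=False, compare=False)
    edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.first_center_ms <= 0 or self.ratio <= 1:
            raise ValueError("grid requires first_center_ms > 0 and ratio > 1")
        k = np.arange(self.n_bins)
        centers = self.first_center_ms * self.ratio**k
        sqrt_r = np.sqrt(self.ratio)
        # geometric midpoints; outer edges continue the same ratio
        edges = np.concatenate([[centers[0] / sqrt_r], centers * sqrt_r])
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "edges", edges)

    def assign(self, intervals_ms: np.ndarray) -> np.ndarray:
        """Bin index for each interval; out-of-range values clip to end bins."""
        idx = np.searchsorted(self.edges, intervals_ms, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


DEFAULT_GRID = BinGrid()
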