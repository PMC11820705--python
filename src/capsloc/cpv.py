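"""Composite predicted value (CPV) encoding.

The CPV collapses a frame's three-class probability vector into one
scalar by weighting each class probability with its positional code
along the alimentary tract:

    CPV = 1·p(stomach) + 2·p(small intestine) + 3·p(large intestine)

A frame confidently in the stomach scores near 1, the small intestine
near 2, the large intestine near 3; mixed or uncertain frames fall in
between.  The CPV is linear in the probability vector and always lies
in the closed interval [1, 3].
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import ProbabilityStream

#: Positional codes for (stomach, small intestine, large intestine).
POSITION_CODES = np.array([1.0, 2.0, 3.0])


@dataclasses.dataclass(frozen=True)
class CPVSeries:
    """Per-frame composite predicted values for one video."""

    video_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("CPV series must be a non-empty 1-D array")
        if np.any(values < 1.0 - 1e-9) or np.any(values > 3.0 + 1e-9):
            raise ValueError("CPV values must lie in [1, 3]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def compute_cpv(probs) -> float:
    """CPV of a single probability vector.

    >>> compute_cpv([0.2, 0.5, 0.3])
    2.1
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return float(p @ POSITION_CODES)


def compute_cpv_series(stream: ProbabilityStream) -> CPVSeries:
    """CPV of every frame of a stream; length is preserved."""
    return CPVSeries(
        video_id=stream.video_id, values=stream.probs @ POSITION_CODES
    )
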