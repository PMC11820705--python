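"""Synthetic per-frame probability streams with known ground truth.

Real capsule-endoscopy probability streams cannot be redistributed, so
the pipeline is exercised on simulated ones.  A video is modelled as
three consecutive segments — stomach, small intestine, large
intestine — separated by two ground-truth boundary frames.  Each
frame's *emitted* (argmax) class is drawn from the row of a 3×3
confusion matrix belonging to the frame's true organ, emulating a
frame classifier with a known error structure; near a boundary the row
is blended 50/50 with the neighbouring organ's row to mimic the
ambiguous mucosa at organ intersections.  Optional misclassification
*bursts* overwrite runs of frames with a wrong organ's row, emulating
sustained confusions (debris, stool, atypical villous structure)
rather than isolated flickers.

The soft probability vector of a frame is a Dirichlet draw
concentrated on the emitted class, so downstream code sees realistic
soft classifier outputs, not one-hot labels.  Everything is
reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io import (
    GroundTruthAnnotation,
    ProbabilityStream,
    write_annotations,
    write_probability_stream,
)

#: Default segment proportions (stomach, small intestine, large intestine),
#: approximating the class balance of a typical full examination.
DEFAULT_SEGMENT_FRACTIONS = (0.10, 0.79, 0.11)


def uniform_confusion(error_rate: float) -> np.ndarray:
    """Row-stochastic confusion matrix with symmetric off-diagonal errors.

    Each true class keeps ``1 - error_rate`` of its mass and spreads
    ``error_rate`` evenly over the other two classes.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    m = np.full((3, 3), error_rate / 2.0)
    np.fill_diagonal(m, 1.0 - error_rate)
    return m


def default_boundaries(n_frames: int) -> tuple[int, int]:
    f1, f2 = DEFAULT_SEGMENT_FRACTIONS[0], sum(DEFAULT_SEGMENT_FRACTIONS[:2])
    return int(round(n_frames * f1)), int(round(n_frames * f2))


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Layout and noise structure of one synthetic examination video.

    n_frames, boundaries
        Total frame count and the two true transition frames
        (stomach→SI, SI→LI); by default the segments occupy roughly
        10% / 79% / 11% of the video.
    confusion
        3×3 row-stochastic matrix; row = true organ, column = emitted
        argmax organ.
    concentration
        Dirichlet concentration on the emitted class (default 20);
        larger values give more confident probability vectors.
    boundary_blur
        Half-width in frames of the ambiguous zone around each
        boundary where the confusion row is blended 50/50 with the
        adjacent organ's row (default 100).
    burst_rate, burst_len
        Expected number of misclassification bursts per 10,000 frames
        (default 0 = none) and the length of each burst in frames.
    """

    n_frames: int
    boundaries: tuple[int, int] | None = None
    confusion: np.ndarray | None = None
    concentration: float = 20.0
    boundary_blur: int = 100
    burst_rate: float = 0.0
    burst_len: int = 50
    seed: int = 0

    def resolved_boundaries(self) -> tuple[int, int]:
        b = self.boundaries or default_boundaries(self.n_frames)
        b1, b2 = int(b[0]), int(b[1])
        if not 0 < b1 < b2 < self.n_frames:
            raise ValueError(
                f"boundaries must satisfy 0 < {b1} < {b2} < {self.n_frames}"
            )
        return b1, b2

    def resolved_confusion(self) -> np.ndarray:
        m = (
            np.eye(3)
            if self.confusion is None
            else np.asarray(self.confusion, dtype=float)
        )
        if m.shape != (3, 3) or np.any(m < 0):
            raise ValueError("confusion must be a non-negative 3×3 matrix")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("confusion rows must each sum to 1")
        return m

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be at least 3")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.boundary_blur < 0 or self.burst_rate < 0 or self.burst_len < 1:
            raise ValueError("invalid noise parameters")
        self.resolved_boundaries()
        self.resolved_confusion()


@dataclasses.dataclass(frozen=True)
class SyntheticCase:
    """A simulated stream paired with its ground-truth annotation."""

    stream: ProbabilityStream
    truth: GroundTruthAnnotation


def true_classes(config: SimulationConfig) -> np.ndarray:
    """Per-frame true organ codes 1/2/3 under the segment layout."""
    b1, b2 = config.resolved_boundaries()
    labels = np.full(config.n_frames, 2, dtype=int)
    labels[:b1] = 1
    labels[b2:] = 3
    return labels


def _emission_rows(config: SimulationConfig) -> np.ndarray:
    """Per-frame confusion row, with 50/50 blending inside blur zones."""
    m = config.resolved_confusion()
    labels = true_classes(config)
    rows = m[labels - 1].copy()
    blur = config.boundary_blur
    if blur > 0:
        b1, b2 = config.resolved_boundaries()
        idx = np.arange(config.n_frames)
        for boundary, lo_class, hi_class in ((b1, 1, 2), (b2, 2, 3)):
            zone = np.abs(idx - boundary) < blur
            blended = 0.5 * (m[lo_class - 1] + m[hi_class - 1])
            rows[zone] = blended
    return rows


def generate_stream(
    config: SimulationConfig, video_id: str = "synthetic"
) -> SyntheticCase:
    """Draw one synthetic probability stream; reproducible from the seed.

    For each frame an emitted class is sampled from its confusion row,
    then a unit-sum probability vector is drawn from a Dirichlet
    concentrated on the emitted class (the largest component is placed
    on the emitted class, so the argmax always equals the draw).
    """
    rng = np.random.default_rng(config.seed)
    b1, b2 = config.resolved_boundaries()
    rows = _emission_rows(config)

    # Emitted (argmax) class per frame: inverse-CDF draw per row.
    u = rng.random(config.n_frames)
    cdf = np.cumsum(rows, axis=1)
    emitted = 1 + (u[:, None] >= cdf).sum(axis=1)

    # Sustained misclassification bursts at Poisson-spaced positions.
    if config.burst_rate > 0:
        n_bursts = rng.poisson(config.burst_rate * config.n_frames / 10_000)
        m = config.resolved_confusion()
        truth = true_classes(config)
        for _ in range(n_bursts):
            start = int(rng.integers(0, config.n_frames))
            stop = min(start + config.burst_len, config.n_frames)
            wrong = int(rng.choice([c for c in (1, 2, 3) if c != truth[start]]))
            seg_u = rng.random(stop - start)
            seg_cdf = np.cumsum(m[wrong - 1])
            emitted[start:stop] = 1 + (seg_u[:, None] >= seg_cdf).sum(axis=1)

    # Soft probabilities: Dirichlet peaked on the emitted class.
    probs = rng.gamma(shape=1.0, size=(config.n_frames, 3))
    peak = rng.gamma(shape=config.concentration, size=config.n_frames)
    # Replace the emitted component by the concentrated gamma draw, then
    # swap the row maximum into the emitted slot so argmax == emitted.
    probs[np.arange(config.n_frames), emitted - 1] = peak
    probs /= probs.sum(axis=1, keepdims=True)
    argmax = probs.argmax(axis=1)
    rows_idx = np.arange(config.n_frames)
    maxvals = probs[rows_idx, argmax].copy()
    emvals = probs[rows_idx, emitted - 1].copy()
    probs[rows_idx, argmax] = emvals
    probs[rows_idx, emitted - 1] = maxvals

    stream = ProbabilityStream(video_id=video_id, probs=probs)
    truth_ann = GroundTruthAnnotation(
        video_id=video_id, stp_stomach_si=b1, stp_si_li=b2
    )
    return SyntheticCase(stream=stream, truth=truth_ann)


def subsample_count(n_images: int, ratio_denominator: int) -> int:
    """Training images retained when sampling 1 in ``ratio_denominator``.

    Uses floor semantics: ``floor(n_images / ratio_denominator)``.
    """
    if n_images < 1 or ratio_denominator < 1:
        raise ValueError("both arguments must be positive")
    return n_images // ratio_denominator


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a small battery of synthetic cases for end-to-end testing.

    Emits four stream CSVs — clean, blurred-boundary, bursty and
    no-transition — plus one annotation CSV covering the three
    transition-bearing cases (the no-transition stream has no valid
    landmarks by construction).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 12_000
    configs = {
        "clean": SimulationConfig(
            n_frames=n, boundary_blur=0, concentration=200.0, seed=seed
        ),
        "blurred": SimulationConfig(
            n_frames=n,
            confusion=uniform_confusion(0.05),
            boundary_blur=100,
            seed=seed + 1,
        ),
        "bursty": SimulationConfig(
            n_frames=n,
            confusion=uniform_confusion(0.05),
            boundary_blur=100,
            burst_rate=1.0,
            burst_len=300,
            seed=seed + 2,
        ),
    }
    paths: list[Path] = []
    annotations = []
    for name, cfg in configs.items():
        case = generate_stream(cfg, video_id=name)
        p = out_dir / f"{name}.csv"
        write_probability_stream(case.stream, p)
        annotations.append(case.truth)
        paths.append(p)

    # Capsule retained in the small intestine: constant segment, no truth.
    rng = np.random.default_rng(seed + 3)
    probs = rng.dirichlet([1.0, 200.0, 1.0], size=4000)
    flat = ProbabilityStream(video_id="no_transition", probs=probs)
    p = out_dir / "no_transition.csv"
    write_probability_stream(flat, p)
    paths.append(p)

    ann_path = out_dir / "annotations.csv"
    write_annotations(annotations, ann_path)
    paths.append(ann_path)
    return paths
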