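"""Reading and writing probability streams, annotations and results.

A *probability stream* is the contract between any upstream frame
classifier and this package: one row per video frame carrying the
classifier's softmax probabilities for the three organ classes
(stomach, small intestine, large intestine).  Streams are stored as
CSV/TSV with header ``frame,p_stomach,p_small_intestine,p_large_intestine``
or as JSON-lines with the same keys.

Frame indices are 0-based and must be contiguous; class codes are
1 (stomach), 2 (small intestine), 3 (large intestine) and the hard
label of a frame is the argmax of its probability vector, ties broken
toward the lower code.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical class order; positional codes are 1-based: stomach=1, ...
CLASS_NAMES = ("stomach", "small_intestine", "large_intestine")
CLASS_CODES = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}

PROB_COLUMNS = ("p_stomach", "p_small_intestine", "p_large_intestine")

#: Probability rows whose sum deviates from 1 by more than this are rejected.
RENORM_TOL = 1e-3


class StreamFormatError(ValueError):
    """The file does not conform to the probability-stream layout."""


class StreamIntegrityError(ValueError):
    """The file parses but violates a stream invariant (e.g. gaps)."""


@dataclasses.dataclass(frozen=True)
class ProbabilityStream:
    """Ordered per-frame class probabilities for one examination video.

    Parameters
    ----------
    video_id : str
        Identifier of the source video.
    probs : ndarray of shape (n_frames, 3)
        Row ``i`` holds the probabilities of frame ``i`` for
        (stomach, small intestine, large intestine).  Rows are
        non-negative and sum to 1 within 1e-6.
    fps : float, optional
        Frame rate; when present, detected frame indices can be
        converted to seconds.
    """

    video_id: str
    probs: np.ndarray
    fps: float | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise StreamFormatError(
                f"probs must have shape (n, 3), got {probs.shape}"
            )
        if probs.shape[0] == 0:
            raise StreamIntegrityError("probability stream must be non-empty")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"probabilities of frame {bad} sum to {sums[bad]:.6g}, not 1"
            )
        if self.fps is not None and self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def n_frames(self) -> int:
        return self.probs.shape[0]

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(self.n_frames)

    @property
    def predicted_class(self) -> np.ndarray:
        """Hard labels as codes 1..3; argmax, ties toward the lower code."""
        # np.argmax returns the first maximum, which is the lower code.
        return np.argmax(self.probs, axis=1) + 1

    def to_frame(self) -> pd.DataFrame:
        """Return the stream as a DataFrame in the canonical column layout."""
        df = pd.DataFrame(self.probs, columns=list(PROB_COLUMNS))
        df.insert(0, "frame", self.frame_index)
        return df


@dataclasses.dataclass(frozen=True)
class GroundTruthAnnotation:
    """Endoscopist-annotated transition frames for one video.

    ``stp_stomach_si`` and ``stp_si_li`` are the standard time points
    (frame indices) of the stomach→small-intestine and
    small-intestine→large-intestine intersections.
    """

    video_id: str
    stp_stomach_si: int
    stp_si_li: int

    def __post_init__(self) -> None:
        if self.stp_stomach_si < 0:
            raise ValueError("stp_stomach_si must be non-negative")
        if not self.stp_stomach_si < self.stp_si_li:
            raise ValueError(
                f"annotation for {self.video_id!r}: stomach–SI landmark "
                f"({self.stp_stomach_si}) must precede SI–LI landmark "
                f"({self.stp_si_li})"
            )

    def validate_against(self, stream: ProbabilityStream) -> None:
        if self.stp_si_li >= stream.n_frames:
            raise ValueError(
                f"landmark {self.stp_si_li} outside stream of length "
                f"{stream.n_frames}"
            )


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in {"csv", "tsv", "jsonl"}:
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    return {".tsv": "tsv", ".jsonl": "jsonl"}.get(suffix, "csv")


def read_probability_stream(
    path: str | Path,
    dialect: str | None = None,
    video_id: str | None = None,
    fps: float | None = None,
) -> ProbabilityStream:
    """Read a per-frame probability stream from CSV, TSV or JSON-lines.

    Rows whose probabilities sum to within ``RENORM_TOL`` of 1 are
    renormalized (classifier outputs are float-rounded in files);
    larger deviations raise a ``ValueError`` naming the row.

    Raises
    ------
    StreamFormatError
        Missing columns or malformed rows.
    StreamIntegrityError
        Frame indices not contiguous from 0.
    """
    path = Path(path)
    kind = _infer_dialect(path, dialect)
    if kind == "jsonl":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise StreamFormatError(
                        f"{path}: line {lineno} is not valid JSON"
                    ) from exc
        df = pd.DataFrame.from_records(records)
    else:
        sep = "\t" if kind == "tsv" else ","
        df = pd.read_csv(path, sep=sep)

    required = ("frame", *PROB_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing columns {missing}")

    frames = df["frame"].to_numpy()
    if len(frames) == 0:
        raise StreamIntegrityError(f"{path}: stream has no frames")
    if not np.array_equal(frames, np.arange(len(frames))):
        raise StreamIntegrityError(
            f"{path}: frame indices must be contiguous from 0"
        )

    probs = df[list(PROB_COLUMNS)].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > RENORM_TOL):
        bad = int(np.argmax(off))
        raise ValueError(
            f"{path}: probabilities of frame {bad} sum to {sums[bad]:.6g} "
            f"(deviation > {RENORM_TOL:g}); data considered corrupt"
        )
    probs = probs / sums[:, None]

    return ProbabilityStream(
        video_id=video_id or path.stem, probs=probs, fps=fps
    )


def write_probability_stream(
    stream: ProbabilityStream, path: str | Path, dialect: str | None = None
) -> None:
    """Write a stream so that :func:`read_probability_stream` round-trips it.

    Probabilities are written at 12 significant digits, which is far
    inside the reader's renormalization tolerance.
    """
    path = Path(path)
    kind = _infer_dialect(path, dialect)
    df = stream.to_frame()
    if kind == "jsonl":
        with open(path, "w") as fh:
            for rec in df.itertuples(index=False):
                fh.write(
                    json.dumps(
                        {
                            "frame": int(rec.frame),
                            "p_stomach": float(rec.p_stomach),
                            "p_small_intestine": float(rec.p_small_intestine),
                            "p_large_intestine": float(rec.p_large_intestine),
                        }
                    )
                    + "\n"
                )
    else:
        sep = "\t" if kind == "tsv" else ","
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_annotations(path: str | Path) -> list[GroundTruthAnnotation]:
    """Read a CSV of endoscopist landmarks, one row per video.

    Expected header: ``video_id,stp_stomach_si,stp_si_li``.
    """
    df = pd.read_csv(path)
    required = ("video_id", "stp_stomach_si", "stp_si_li")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing columns {missing}")
    return [
        GroundTruthAnnotation(
            video_id=str(row.video_id),
            stp_stomach_si=int(row.stp_stomach_si),
            stp_si_li=int(row.stp_si_li),
        )
        for row in df.itertuples(index=False)
    ]


def write_annotations(
    annotations: Iterable[GroundTruthAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (a.video_id, a.stp_stomach_si, a.stp_si_li)
            for a in annotations
        ],
        columns=["video_id", "stp_stomach_si", "stp_si_li"],
    )
    df.to_csv(path, index=False)


def stream_from_arrays(
    probs: Sequence[Sequence[float]] | np.ndarray,
    video_id: str = "stream",
    fps: float | None = None,
) -> ProbabilityStream:
    """Convenience constructor from any (n, 3) array-like of probabilities."""
    return ProbabilityStream(video_id=video_id, probs=np.asarray(probs, float), fps=fps)
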