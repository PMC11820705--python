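"""Evaluation metrics for localization and frame classification.

Localization quality is measured against endoscopist landmarks by the
number of error frames NEF = |STP − OPTP| (annotated vs detected frame)
per intersection, aggregated across videos as its mean (MAEF) and
median (MdAEF).  Classification quality is measured by per-class
precision TP / (TP + FP).  A reporting helper computes the average
reduction in error between two post-processing variants from paired
per-model totals.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .io import GroundTruthAnnotation
from .localize import LocalizationResult


class UndefinedMetricError(ZeroDivisionError):
    """Metric has no value on this input (e.g. precision with TP+FP=0)."""


def precision(tp: int, fp: int) -> float:
    """Per-class precision TP / (TP + FP).

    Raises :class:`UndefinedMetricError` when no frame was predicted
    positive — never silently returns 0.
    """
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise UndefinedMetricError(
            "precision undefined: no positive predictions"
        )
    return tp / (tp + fp)


def per_class_precision(
    true_classes: Sequence[int], predicted_classes: Sequence[int]
) -> dict[int, float]:
    """Frame-level precision per organ class (codes 1, 2, 3).

    Classes never predicted are omitted from the result rather than
    scored 0.
    """
    t = np.asarray(true_classes)
    p = np.asarray(predicted_classes)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    out: dict[int, float] = {}
    for c in (1, 2, 3):
        predicted = p == c
        if predicted.any():
            tp = int(np.sum(predicted & (t == c)))
            out[c] = precision(tp, int(predicted.sum()) - tp)
    return out


def nef(stp: int, optp: int) -> int:
    """Number of error frames between annotated and detected time point."""
    return abs(int(stp) - int(optp))


def aggregate(nefs: Sequence[float]) -> tuple[float, float]:
    """(MAEF, MdAEF): mean and median of NEF values across videos."""
    arr = np.asarray(nefs, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty NEF list")
    return float(arr.mean()), float(np.median(arr))


def ablation_reduction(
    metric_alone: Sequence[float], metric_variant: Sequence[float]
) -> float:
    """Average per-model error reduction of a variant, rounded to frames.

    Given paired totals (one per backbone model) for a bare variant and
    an augmented variant, returns round(mean(alone − variant)), half
    away from zero, matching whole-frame reporting.
    """
    a = np.asarray(metric_alone, dtype=float)
    b = np.asarray(metric_variant, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("inputs must be equal-length non-empty sequences")
    mean = float(np.mean(a - b))
    return float(math.floor(mean + 0.5) if mean >= 0 else math.ceil(mean - 0.5))


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    """Per-video and aggregate localization errors.

    ``maef``/``mdaef`` aggregate per intersection; the ``total_*``
    figures are the sums of the two per-intersection aggregates.
    Videos where the localizer found no intersection are excluded from
    the aggregates and listed in ``failures``.
    """

    per_video_nef: Mapping[str, tuple[int | None, int | None]]
    maef_iss: float | None
    mdaef_iss: float | None
    maef_isl: float | None
    mdaef_isl: float | None
    failures: tuple[str, ...] = ()
    per_class_precision: Mapping[int, float] | None = None

    @property
    def total_maef(self) -> float | None:
        if self.maef_iss is None or self.maef_isl is None:
            return None
        return self.maef_iss + self.maef_isl

    @property
    def total_mdaef(self) -> float | None:
        if self.mdaef_iss is None or self.mdaef_isl is None:
            return None
        return self.mdaef_iss + self.mdaef_isl

    def to_dict(self) -> dict:
        return {
            "per_video_nef": {
                k: list(v) for k, v in self.per_video_nef.items()
            },
            "maef_iss": self.maef_iss,
            "mdaef_iss": self.mdaef_iss,
            "maef_isl": self.maef_isl,
            "mdaef_isl": self.mdaef_isl,
            "total_maef": self.total_maef,
            "total_mdaef": self.total_mdaef,
            "failures": list(self.failures),
            "per_class_precision": (
                {str(k): v for k, v in self.per_class_precision.items()}
                if self.per_class_precision is not None
                else None
            ),
        }


def evaluate_localizations(
    results: Sequence[LocalizationResult],
    annotations: Sequence[GroundTruthAnnotation],
    per_class_prec: Mapping[int, float] | None = None,
) -> EvaluationReport:
    """Pair detections with annotations by video_id and aggregate errors."""
    truth = {a.video_id: a for a in annotations}
    per_video: dict[str, tuple[int | None, int | None]] = {}
    nefs_iss: list[int] = []
    nefs_isl: list[int] = []
    failures: list[str] = []
    for res in results:
        ann = truth.get(res.video_id)
        if ann is None:
            raise KeyError(f"no annotation for video {res.video_id!r}")
        e_iss = (
            nef(ann.stp_stomach_si, res.iss_frame)
            if res.iss_frame is not None
            else None
        )
        e_isl = (
            nef(ann.stp_si_li, res.isl_frame)
            if res.isl_frame is not None
            else None
        )
        per_video[res.video_id] = (e_iss, e_isl)
        if e_iss is None or e_isl is None:
            failures.append(res.video_id)
        if e_iss is not None:
            nefs_iss.append(e_iss)
        if e_isl is not None:
            nefs_isl.append(e_isl)

    maef_iss, mdaef_iss = aggregate(nefs_iss) if nefs_iss else (None, None)
    maef_isl, mdaef_isl = aggregate(nefs_isl) if nefs_isl else (None, None)
    return EvaluationReport(
        per_video_nef=per_video,
        maef_iss=maef_iss,
        mdaef_iss=mdaef_iss,
        maef_isl=maef_isl,
        mdaef_isl=mdaef_isl,
        failures=tuple(failures),
        per_class_precision=per_class_prec,
    )
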