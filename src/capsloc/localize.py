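"""OPLA — organ-position localization by sliding-window thresholding.

The denoised CPV (NCPV) sequence of a full examination video is
aggregated into overlapping *waiting areas* (WAs): windows of ``was``
frames advancing by ``wass`` frames.  The mean NCPV of each WA — the
waiting-area average value (WAAV) — is a smooth trajectory that rises
from ≈1 (stomach) through ≈2 (small intestine) toward ≈3 (large
intestine) as the capsule advances.

A transition is declared at the first window where the WAAV crosses a
threshold from below *and stays there*: the candidate window is still
sub-threshold, the next window is supra-threshold, and the mean of the
following ``continuity`` windows exceeds the threshold, so isolated
spikes cannot fire a detection.  The stomach→small-intestine
intersection (ISS) uses threshold ``st`` with continuity ``sct``; the
small-intestine→large-intestine intersection (ISL) uses ``lt`` and
``lct`` and is searched only after the ISS to enforce anatomical
ordering.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .denoise import NCPVSeries


class InsufficientDataError(ValueError):
    """The video is shorter than one waiting area."""


@dataclasses.dataclass(frozen=True)
class OPLAParams:
    """Thresholding parameters of the localization algorithm.

    was, wass
        Waiting-area size and slide, in frames (defaults 200 / 100).
    st, lt
        WAAV thresholds for the stomach→SI and SI→LI crossings
        (defaults 1.35 and 2.4, on the CPV scale 1–3).
    sct, lct
        Continuity counts: number of subsequent windows whose mean
        WAAV must exceed the threshold to confirm a crossing
        (default 8 each).
    report
        Which frame of the detected window is reported: ``"start"``
        (the start frame of the first supra-threshold window, default)
        or ``"center"``.
    """

    was: int = 200
    wass: int = 100
    st: float = 1.35
    lt: float = 2.4
    sct: int = 8
    lct: int = 8
    report: str = "start"

    def __post_init__(self) -> None:
        if self.was < 1 or self.wass < 1:
            raise ValueError("was and wass must be positive")
        if self.wass > self.was:
            raise ValueError("wass must not exceed was")
        if not 1.0 < self.st < self.lt < 3.0:
            raise ValueError("thresholds must satisfy 1 < st < lt < 3")
        if self.sct < 1 or self.lct < 1:
            raise ValueError("continuity counts must be positive")
        if self.report not in {"start", "center"}:
            raise ValueError("report must be 'start' or 'center'")


@dataclasses.dataclass(frozen=True)
class WAAVSeries:
    """Waiting-area averages with their window→frame mapping."""

    values: np.ndarray
    window_starts: np.ndarray
    was: int
    wass: int

    def __len__(self) -> int:
        return self.values.size


@dataclasses.dataclass(frozen=True)
class LocalizationResult:
    """Detected intersection positions for one video.

    Frame indices are 0-based; ``None`` marks a non-detection.
    ``iss_seconds``/``isl_seconds`` are filled only when the stream's
    frame rate is known.
    """

    video_id: str
    iss_frame: int | None
    isl_frame: int | None
    iss_window: int | None
    isl_window: int | None
    iss_seconds: float | None = None
    isl_seconds: float | None = None

    def __post_init__(self) -> None:
        if (
            self.iss_frame is not None
            and self.isl_frame is not None
            and not self.iss_frame < self.isl_frame
        ):
            raise ValueError("ISS frame must precede ISL frame")


def n_windows(n_frames: int, was: int, wass: int) -> int:
    """Number of complete waiting areas: floor((N − was)/wass) + 1."""
    if n_frames < was:
        return 0
    return (n_frames - was) // wass + 1


def compute_waav(ncpv: NCPVSeries, params: OPLAParams = OPLAParams()) -> WAAVSeries:
    """Mean NCPV over each complete waiting area.

    Windows start at 0, wass, 2·wass, …; an incomplete trailing window
    is dropped.  Raises :class:`InsufficientDataError` when the video
    is shorter than one window.
    """
    x = ncpv.values
    count = n_windows(x.size, params.was, params.wass)
    if count == 0:
        raise InsufficientDataError(
            f"need at least {params.was} frames for one waiting area, "
            f"got {x.size}"
        )
    starts = np.arange(count) * params.wass
    csum = np.concatenate([[0.0], np.cumsum(x)])
    values = (csum[starts + params.was] - csum[starts]) / params.was
    return WAAVSeries(
        values=values, window_starts=starts, was=params.was, wass=params.wass
    )


def locate_crossing(
    waav: WAAVSeries,
    threshold: float,
    continuity: int,
    search_from: int = 0,
) -> int | None:
    """First sustained upward threshold crossing of the WAAV trajectory.

    Returns the smallest window index ``i >= search_from`` such that

    * ``waav[i] < threshold``        (still below),
    * ``waav[i+1] >= threshold``     (crossed), and
    * ``mean(waav[i+1 : i+1+continuity]) > threshold``  (stayed above),

    requiring all ``continuity`` follow-up windows to exist.  Returns
    ``None`` when no window qualifies; absence is a valid outcome
    (e.g. the capsule never left the organ).
    """
    v = waav.values
    n = v.size
    for i in range(max(search_from, 0), n - continuity):
        if v[i] < threshold and v[i + 1] >= threshold:
            if v[i + 1 : i + 1 + continuity].mean() > threshold:
                return i
    return None


def _window_to_frame(window: int, params: OPLAParams) -> int:
    # Report the first supra-threshold window (window + 1).
    start = (window + 1) * params.wass
    if params.report == "center":
        return start + params.was // 2
    return start


def locate_intersections(
    ncpv: NCPVSeries,
    params: OPLAParams = OPLAParams(),
    fps: float | None = None,
) -> LocalizationResult:
    """Detect the ISS and ISL intersections on a denoised CPV series.

    The ISS is searched from the first window with threshold ``st`` /
    continuity ``sct``; the ISL search starts strictly after the ISS
    window (or from the first window when no ISS was found) with
    ``lt`` / ``lct``.
    """
    waav = compute_waav(ncpv, params)

    iss_w = locate_crossing(waav, params.st, params.sct, search_from=0)
    isl_from = iss_w + 1 if iss_w is not None else 0
    isl_w = locate_crossing(waav, params.lt, params.lct, search_from=isl_from)

    iss_frame = _window_to_frame(iss_w, params) if iss_w is not None else None
    isl_frame = _window_to_frame(isl_w, params) if isl_w is not None else None

    return LocalizationResult(
        video_id=ncpv.video_id,
        iss_frame=iss_frame,
        isl_frame=isl_frame,
        iss_window=iss_w,
        isl_window=isl_w,
        iss_seconds=(iss_frame / fps if fps and iss_frame is not None else None),
        isl_seconds=(isl_frame / fps if fps and isl_frame is not None else None),
    )
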