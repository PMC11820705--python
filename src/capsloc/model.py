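"""Model/Results surface tying the pipeline stages together.

:class:`CapsuleLocalizer` is constructed from a probability stream (or
a DataFrame / CSV in the canonical layout) plus pipeline parameters;
``fit()`` runs CPV encoding → windowed k-means outlier correction →
sliding-window threshold localization and returns a
:class:`LocalizerResults` carrying the detected intersections, every
intermediate series, the per-window threshold decision log and a
``summary()`` table.  The localizer's temporal resolution is one
window slide (WASS frames), which the summary reports alongside the
estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .cpv import CPVSeries, compute_cpv_series
from .denoise import DenoiserParams, NCPVSeries, denoise_series
from .io import GroundTruthAnnotation, ProbabilityStream, read_probability_stream
from .localize import (
    LocalizationResult,
    OPLAParams,
    WAAVSeries,
    compute_waav,
)
from .metrics import nef

logger = logging.getLogger("capsloc")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Bundled parameters of the full localization pipeline."""

    denoiser: DenoiserParams = DenoiserParams()
    opla: OPLAParams = OPLAParams()
    fps: float | None = None
    use_denoiser: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        return cls(
            denoiser=DenoiserParams(**raw.get("denoiser", {})),
            opla=OPLAParams(**raw.get("opla", {})),
            fps=raw.get("fps"),
            use_denoiser=raw.get("use_denoiser", True),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "denoiser": dataclasses.asdict(self.denoiser),
            "opla": dataclasses.asdict(self.opla),
            "fps": self.fps,
            "use_denoiser": self.use_denoiser,
        }


class CapsuleLocalizer:
    """Locate the two alimentary-tract transitions in one video.

    Parameters
    ----------
    stream : ProbabilityStream
        Per-frame organ-classification probabilities.
    config : PipelineConfig, optional
        Denoiser and localization parameters; defaults follow the
        published hyperparameter setting (box 200/stride 200;
        WAS 200, WASS 100, ST 1.35, LT 2.4, SCT = LCT = 8).
    """

    def __init__(
        self, stream: ProbabilityStream, config: PipelineConfig | None = None
    ) -> None:
        self.stream = stream
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        video_id: str = "stream",
        fps: float | None = None,
        config: PipelineConfig | None = None,
    ) -> "CapsuleLocalizer":
        """Build from a DataFrame with the canonical stream columns."""
        from .io import PROB_COLUMNS

        missing = [c for c in PROB_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing probability columns {missing}")
        stream = ProbabilityStream(
            video_id=video_id,
            probs=df[list(PROB_COLUMNS)].to_numpy(float),
            fps=fps,
        )
        return cls(stream, config)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fps: float | None = None,
        config: PipelineConfig | None = None,
    ) -> "CapsuleLocalizer":
        return cls(read_probability_stream(path, fps=fps), config)

    def fit(self) -> "LocalizerResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        cpv = compute_cpv_series(self.stream)
        if cfg.use_denoiser:
            ncpv = denoise_series(cpv, cfg.denoiser)
        else:
            ncpv = NCPVSeries(video_id=cpv.video_id, values=cpv.values.copy())
        waav = compute_waav(ncpv, cfg.opla)
        logger.info(
            "%s: %d frames -> %d waiting areas (WAS=%d, WASS=%d)",
            self.stream.video_id,
            self.stream.n_frames,
            len(waav),
            cfg.opla.was,
            cfg.opla.wass,
        )

        decisions: list[dict[str, Any]] = []
        iss_w = self._logged_crossing(
            waav, cfg.opla.st, cfg.opla.sct, 0, "stomach->small_intestine",
            decisions,
        )
        isl_from = iss_w + 1 if iss_w is not None else 0
        isl_w = self._logged_crossing(
            waav, cfg.opla.lt, cfg.opla.lct, isl_from,
            "small_intestine->large_intestine", decisions,
        )

        fps = cfg.fps if cfg.fps is not None else self.stream.fps

        def frame_of(w: int | None) -> int | None:
            if w is None:
                return None
            start = (w + 1) * cfg.opla.wass
            if cfg.opla.report == "center":
                return start + cfg.opla.was // 2
            return start

        iss_frame, isl_frame = frame_of(iss_w), frame_of(isl_w)
        result = LocalizationResult(
            video_id=self.stream.video_id,
            iss_frame=iss_frame,
            isl_frame=isl_frame,
            iss_window=iss_w,
            isl_window=isl_w,
            iss_seconds=(iss_frame / fps if fps and iss_frame is not None else None),
            isl_seconds=(isl_frame / fps if fps and isl_frame is not None else None),
        )
        return LocalizerResults(
            model=self, cpv=cpv, ncpv=ncpv, waav=waav, result=result,
            decisions=decisions,
        )

    @staticmethod
    def _logged_crossing(
        waav: WAAVSeries,
        threshold: float,
        continuity: int,
        search_from: int,
        label: str,
        decisions: list[dict[str, Any]],
    ) -> int | None:
        v = waav.values
        for i in range(max(search_from, 0), len(v) - continuity):
            below = v[i] < threshold
            crossed = v[i + 1] >= threshold
            if not (below and crossed):
                continue
            follow = float(v[i + 1 : i + 1 + continuity].mean())
            ok = follow > threshold
            decisions.append(
                {
                    "transition": label,
                    "window": i,
                    "waav": float(v[i]),
                    "next_waav": float(v[i + 1]),
                    "continuity_mean": follow,
                    "threshold": threshold,
                    "accepted": ok,
                }
            )
            logger.debug(
                "%s candidate window %d: waav=%.3f next=%.3f "
                "continuity_mean=%.3f thr=%.2f -> %s",
                label, i, v[i], v[i + 1], follow, threshold,
                "accept" if ok else "reject",
            )
            if ok:
                return i
        return None


@dataclasses.dataclass
class LocalizerResults:
    """Fitted pipeline output: estimates, intermediates and diagnostics."""

    model: CapsuleLocalizer
    cpv: CPVSeries
    ncpv: NCPVSeries
    waav: WAAVSeries
    result: LocalizationResult
    decisions: list[dict[str, Any]]

    @property
    def iss_frame(self) -> int | None:
        return self.result.iss_frame

    @property
    def isl_frame(self) -> int | None:
        return self.result.isl_frame

    @property
    def resolution_frames(self) -> int:
        """Temporal resolution of the estimates: one window slide."""
        return self.waav.wass

    def nef_against(
        self, truth: GroundTruthAnnotation
    ) -> tuple[int | None, int | None]:
        """Error frames vs an annotation, per intersection (None = missed)."""
        e_iss = (
            nef(truth.stp_stomach_si, self.result.iss_frame)
            if self.result.iss_frame is not None
            else None
        )
        e_isl = (
            nef(truth.stp_si_li, self.result.isl_frame)
            if self.result.isl_frame is not None
            else None
        )
        return e_iss, e_isl

    def to_dict(self, include_waav: bool = False) -> dict[str, Any]:
        out: dict[str, Any] = {
            "video_id": self.result.video_id,
            "iss_frame": self.result.iss_frame,
            "isl_frame": self.result.isl_frame,
            "iss_window": self.result.iss_window,
            "isl_window": self.result.isl_window,
            "iss_seconds": self.result.iss_seconds,
            "isl_seconds": self.result.isl_seconds,
            "n_frames": self.model.stream.n_frames,
            "n_windows": len(self.waav),
            "resolution_frames": self.resolution_frames,
            "config": self.model.config.to_dict(),
            "decisions": self.decisions,
        }
        if include_waav:
            out["waav"] = self.waav.values.tolist()
            out["window_starts"] = self.waav.window_starts.tolist()
        return out

    def to_json(self, path: str | Path, include_waav: bool = False) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_waav=include_waav), fh, indent=2)

    def summary(self) -> str:
        """Human-readable report of the fitted localization."""
        r = self.result
        cfg = self.model.config
        lines = [
            "Capsule localization results",
            "=" * 60,
            f"video_id:          {r.video_id}",
            f"frames:            {self.model.stream.n_frames}",
            f"waiting areas:     {len(self.waav)} "
            f"(WAS={cfg.opla.was}, WASS={cfg.opla.wass})",
            f"resolution:        ±{self.resolution_frames} frames "
            "(one window slide)",
            "-" * 60,
        ]
        for name, frame, window, secs, thr, cont in (
            ("stomach -> small intestine", r.iss_frame, r.iss_window,
             r.iss_seconds, cfg.opla.st, cfg.opla.sct),
            ("small -> large intestine  ", r.isl_frame, r.isl_window,
             r.isl_seconds, cfg.opla.lt, cfg.opla.lct),
        ):
            if frame is None:
                lines.append(f"{name}: not detected "
                             f"(threshold {thr}, continuity {cont})")
            else:
                sec = f", t = {secs:.1f} s" if secs is not None else ""
                lines.append(
                    f"{name}: frame {frame} (window {window}, "
                    f"threshold {thr}, continuity {cont}{sec})"
                )
        lines.append("=" * 60)
        return "\n".join(lines)


def run_pipeline(
    stream_path: str | Path,
    config: PipelineConfig | None = None,
) -> LocalizerResults:
    """Convenience wrapper: read a stream CSV and fit the localizer."""
    model = CapsuleLocalizer.from_csv(stream_path, config=config)
    return model.fit()
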