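"""Timeline colour-bar visualization of a localized video.

Each panel maps a per-frame quantity onto a horizontal gradient bar:
value 1 (stomach) renders red, 2 (small intestine) yellow and
3 (large intestine) blue, with a monotone red→yellow→blue gradient in
between.  Stacked panels show the expert annotation, the hard argmax
labels, the raw and denoised CPV, and the window averages mapped back
to frames, with vertical markers at the detected (and optionally
true) intersections.  Long videos are downsampled to a fixed pixel
budget by per-pixel averaging, so isolated outliers dim rather than
alias away.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

#: Monotone gradient anchored at 1=red, 2=yellow, 3=blue.
ORGAN_CMAP = LinearSegmentedColormap.from_list(
    "organ", [(0.0, "#d62728"), (0.5, "#ffdf00"), (1.0, "#1f77b4")]
)

#: Pixel budget for the frame axis of each bar.
MAX_PIXELS = 2000


def downsample_series(values: np.ndarray, max_pixels: int = MAX_PIXELS) -> np.ndarray:
    """Average consecutive frames down to at most ``max_pixels`` bins."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n <= max_pixels:
        return x
    edges = np.linspace(0, n, max_pixels + 1).astype(int)
    sums = np.concatenate([[0.0], np.cumsum(x)])
    widths = np.diff(edges)
    return (sums[edges[1:]] - sums[edges[:-1]]) / widths


def waav_to_frames(
    waav_values: np.ndarray,
    window_starts: np.ndarray,
    was: int,
    n_frames: int,
) -> np.ndarray:
    """Expand window averages back onto the frame axis (mean of covering WAs)."""
    acc = np.zeros(n_frames)
    cnt = np.zeros(n_frames)
    for v, s in zip(waav_values, window_starts):
        acc[s : s + was] += v
        cnt[s : s + was] += 1
    out = np.full(n_frames, np.nan)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    # Frames past the last complete window keep the final WAAV.
    if covered.any():
        last = np.max(np.nonzero(covered))
        out[last + 1 :] = out[last]
    return out


def render_timeline(
    panels: Sequence[tuple[str, np.ndarray]],
    out: str | Path,
    markers: Sequence[tuple[str, int]] = (),
    title: str | None = None,
    dpi: int = 120,
) -> Path:
    """Render stacked gradient bars with intersection markers to a file.

    Parameters
    ----------
    panels
        Ordered (label, per-frame values on the 1–3 scale) pairs; all
        series must share the same length.
    markers
        (label, frame index) pairs drawn as vertical lines across all
        panels.
    """
    if not panels:
        raise ValueError("need at least one panel")
    n = len(panels[0][1])
    for label, series in panels:
        if len(series) != n:
            raise ValueError(
                f"panel {label!r} has length {len(series)}, expected {n}"
            )

    fig, axes = plt.subplots(
        len(panels), 1, figsize=(10, 0.7 * len(panels) + 0.8), squeeze=False,
        sharex=True,
    )
    for ax, (label, series) in zip(axes.ravel(), panels):
        img = downsample_series(np.asarray(series, float))[None, :]
        ax.imshow(
            img,
            aspect="auto",
            cmap=ORGAN_CMAP,
            vmin=1.0,
            vmax=3.0,
            extent=(0, n, 0, 1),
            interpolation="nearest",
        )
        ax.set_yticks([])
        ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=8)
        for mlabel, frame in markers:
            ax.axvline(frame, color="black", lw=1.0, ls="--")
    axes.ravel()[-1].set_xlabel("frame")
    if markers:
        for mlabel, frame in markers:
            axes.ravel()[0].annotate(
                mlabel, (frame, 1.05), fontsize=7, ha="center",
                annotation_clip=False,
            )
    if title:
        fig.suptitle(title, fontsize=10)
    out = Path(out)
    fig.savefig(out, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
    return out


def render_results(results, out: str | Path, truth=None) -> Path:
    """Timeline for a fitted :class:`~capsloc.model.LocalizerResults`."""
    stream = results.model.stream
    n = stream.n_frames
    panels = [
        ("labels", stream.predicted_class.astype(float)),
        ("CPV", results.cpv.values),
        ("NCPV", results.ncpv.values),
        (
            "WAAV",
            waav_to_frames(
                results.waav.values,
                results.waav.window_starts,
                results.waav.was,
                n,
            ),
        ),
    ]
    if truth is not None:
        expert = np.full(n, 2.0)
        expert[: truth.stp_stomach_si] = 1.0
        expert[truth.stp_si_li :] = 3.0
        panels.insert(0, ("expert", expert))
    markers = []
    if results.iss_frame is not None:
        markers.append(("ISS", results.iss_frame))
    if results.isl_frame is not None:
        markers.append(("ISL", results.isl_frame))
    return render_timeline(
        panels, out, markers=markers, title=stream.video_id
    )
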