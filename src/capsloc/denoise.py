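"""Windowed 1-D k-means outlier correction of the CPV series.

Isolated misclassified frames show up as short spikes in the CPV
sequence (a lone "large intestine" frame inside the stomach, say).
The series is cut into boxes of 200 consecutive frames and each box is
clustered into k = 2 scalar clusters.  A box is either homogeneous
(one organ → one tight cluster, or two centroids closer than
``min_centroid_gap``) and passes through unchanged, or it contains a
small minority cluster — at most ``minority_fraction`` of the box —
whose members are treated as outliers and snapped to the dominant
centroid.  Balanced clusters (a genuine organ transition inside the
box) are deliberately left alone.

For k = 2 on scalar data the k-means optimum is attained exactly: the
two clusters are separated by a single cut in sorted order, so the
global minimum-SSE partition is found by a prefix-sum scan over all
sorted-order splits.  This is the optimum that seeded k-means++ with
restarts approximates; computing it directly makes the denoiser fully
deterministic.  For k > 2 the clustering falls back to seeded
k-means++ (scikit-learn).

The corrected sequence is called the NCPV (new CPV) series.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.cluster import KMeans

from .cpv import CPVSeries


@dataclasses.dataclass(frozen=True)
class DenoiserParams:
    """Parameters of the windowed k-means outlier correction.

    box_size, stride
        Length of each clustering box in frames and the advance between
        consecutive boxes.  With the defaults (200/200) boxes tile the
        video without overlap.
    n_clusters
        k for the clustering; 2 separates "dominant organ" from
        "outliers" and is solved exactly.
    seed
        Random seed of the k-means++ initialization used when
        n_clusters > 2; fixed for reproducibility (the exact k = 2
        solver is deterministic and ignores it).
    minority_fraction
        A non-dominant cluster is an outlier cluster only when it holds
        at most this fraction of the box.  Balanced clusters — a real
        transition — survive.
    min_centroid_gap
        Below this centroid separation the box is considered
        homogeneous and left unchanged.
    """

    box_size: int = 200
    stride: int = 200
    n_clusters: int = 2
    seed: int = 0
    minority_fraction: float = 0.1
    min_centroid_gap: float = 0.5

    def __post_init__(self) -> None:
        if self.box_size < 1 or self.stride < 1:
            raise ValueError("box_size and stride must be positive")
        if self.stride > self.box_size:
            raise ValueError("stride must not exceed box_size")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if not 0 < self.minority_fraction <= 0.5:
            raise ValueError("minority_fraction must be in (0, 0.5]")
        if self.min_centroid_gap <= 0:
            raise ValueError("min_centroid_gap must be positive")


@dataclasses.dataclass(frozen=True)
class NCPVSeries:
    """Denoised CPV series; same length as its source CPV series."""

    video_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return self.values.size


def two_means_1d(values) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-means of scalar values: (labels, centroids).

    The optimal 2-partition of scalars under the k-means SSE objective
    is a cut in sorted order; all n−1 cuts are scored with prefix sums
    and the best taken (ties → the cut with the smaller lower
    cluster).  Labels are 0 for the lower cluster, 1 for the upper.
    """
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    c1 = np.cumsum(xs)
    c2 = np.cumsum(xs**2)
    k = np.arange(1, n)  # size of the lower cluster
    sse_lo = c2[k - 1] - c1[k - 1] ** 2 / k
    sse_hi = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    split = int(k[np.argmin(sse_lo + sse_hi)])
    labels = np.empty(n, dtype=int)
    labels[order] = (np.arange(n) >= split).astype(int)
    centroids = np.array(
        [xs[:split].mean(), xs[split:].mean()]
    )
    return labels, centroids


def denoise_box(values, params: DenoiserParams = DenoiserParams()) -> np.ndarray:
    """Outlier-correct one box of scalar CPVs; returns a new array.

    Boxes with fewer than ``n_clusters`` distinct values, fewer than 2
    elements, or centroids closer than ``min_centroid_gap`` are
    returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    out = x.copy()
    if x.size < 2 or np.unique(x).size < params.n_clusters:
        return out

    if params.n_clusters == 2:
        labels, centroids = two_means_1d(x)
    else:
        km = KMeans(
            n_clusters=params.n_clusters,
            init="k-means++",
            n_init=10,
            random_state=params.seed,
        )
        labels = km.fit_predict(x.reshape(-1, 1))
        centroids = km.cluster_centers_.ravel()

    if np.ptp(centroids) < params.min_centroid_gap:
        return out

    counts = np.bincount(labels, minlength=params.n_clusters)
    dominant = int(np.argmax(counts))
    top = np.flatnonzero(counts == counts[dominant])
    if top.size > 1:
        # Tie on size: dominant cluster is the one nearest the box median.
        med = np.median(x)
        dominant = int(top[np.argmin(np.abs(centroids[top] - med))])

    cutoff = params.minority_fraction * x.size
    for c in range(params.n_clusters):
        if c != dominant and 0 < counts[c] <= cutoff:
            out[labels == c] = centroids[dominant]
    return out


def denoise_series(
    cpv: CPVSeries, params: DenoiserParams = DenoiserParams()
) -> NCPVSeries:
    """Apply :func:`denoise_box` over consecutive boxes of the series.

    Boxes start at 0, stride, 2·stride, …; with stride = box_size they
    partition the video.  A final short box of ≥ 2 frames is processed
    as-is; a single trailing frame passes through unchanged.
    """
    x = cpv.values
    out = x.copy()
    n = x.size
    start = 0
    while start < n:
        stop = min(start + params.box_size, n)
        out[start:stop] = denoise_box(x[start:stop], params)
        if stop == n:
            break
        start += params.stride
    return NCPVSeries(video_id=cpv.video_id, values=out)
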