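"""Brute-force reference implementations used only by the tests.

These are deliberately written as naive loops, independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np


def sorted_split_two_means(values):
    """Optimal 1-D 2-means by exhaustive split of the sorted values.

    Returns (labels, centroids, sse): labels are 0 for the lower
    cluster and 1 for the upper cluster, in the original order of
    ``values``.  Among equal-SSE splits the first (smallest lower
    cluster) wins.
    """
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    best = None
    for split in range(1, n):
        lo, hi = xs[:split], xs[split:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, split, lo.mean(), hi.mean())
    sse, split, c_lo, c_hi = best
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[split:] = 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, (c_lo, c_hi), sse


def partition_sse(values, labels):
    """Within-cluster SSE of an arbitrary labelling of scalar values."""
    x = np.asarray(values, dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        member = x[labels == lab]
        total += ((member - member.mean()) ** 2).sum()
    return total


def crossing_scan(waav_values, threshold, continuity, search_from=0):
    """Naive scan for the first sustained upward threshold crossing."""
    v = list(waav_values)
    n = len(v)
    for i in range(n):
        if i < search_from:
            continue
        if i + 1 + continuity > n:
            continue
        if not (v[i] < threshold and v[i + 1] >= threshold):
            continue
        s = 0.0
        for j in range(i + 1, i + 1 + continuity):
            s += v[j]
        if s / continuity > threshold:
            return i
    return None
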