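"""Published benchmark error totals used by the reduction-reporting helper.

Reference MAEF/MdAEF totals (in frames, summed over the two
intersections) for six backbone classifiers evaluated on a 20-video
capsule-endoscopy test set under four post-processing variants:

* ``alone``   — the frame classifier by itself
* ``kmeans``  — classifier + windowed k-means outlier correction
* ``opla``    — classifier + sliding-window threshold localization
* ``combined``— classifier + both post-processing stages

These printed whole-frame totals are inputs to
:func:`capsloc.metrics.ablation_reduction`, which reports how many
frames of error each post-processing stage removes on average.
"""

from __future__ import annotations

import pandas as pd

from .metrics import ablation_reduction

BACKBONES = (
    "swin_transformer",
    "vision_transformer",
    "resnet50",
    "densenet121",
    "inception_v4",
    "vgg19",
)

#: Total MAEF in frames, per backbone (rows follow BACKBONES order).
TOTAL_MAEF = {
    "alone": (83_847, 83_468, 77_978, 84_584, 83_042, 83_666),
    "kmeans": (65_480, 57_928, 7_100, 40_850, 34_764, 64_926),
    "opla": (1_026, 2_690, 2_265, 2_806, 1_558, 2_465),
    "combined": (891, 1_785, 1_809, 2_424, 1_560, 1_878),
}

#: Total MdAEF in frames, per backbone.
TOTAL_MDAEF = {
    "alone": (73_948, 77_603, 70_193, 78_642, 73_203, 76_035),
    "kmeans": (60_802, 46_602, 502, 27_300, 23_272, 66_183),
    "opla": (195, 935, 345, 210, 245, 375),
    "combined": (190, 500, 210, 230, 250, 325),
}


def benchmark_table() -> pd.DataFrame:
    """The reference totals as a tidy DataFrame (frames)."""
    records = []
    for variant in TOTAL_MAEF:
        for backbone, maef, mdaef in zip(
            BACKBONES, TOTAL_MAEF[variant], TOTAL_MDAEF[variant]
        ):
            records.append(
                {
                    "backbone": backbone,
                    "variant": variant,
                    "total_maef": maef,
                    "total_mdaef": mdaef,
                }
            )
    return pd.DataFrame.from_records(records)


def average_reduction(variant: str, metric: str = "maef") -> float:
    """Mean error reduction of a post-processing variant vs classifier alone.

    Averaged over the six backbones and rounded to whole frames.
    """
    table = TOTAL_MAEF if metric == "maef" else TOTAL_MDAEF
    if metric not in {"maef", "mdaef"}:
        raise ValueError("metric must be 'maef' or 'mdaef'")
    if variant not in table:
        raise KeyError(f"unknown variant {variant!r}")
    return ablation_reduction(table["alone"], table[variant])


def backbone_reduction(
    backbone: str, variant: str = "combined", metric: str = "maef"
) -> float:
    """Error reduction of one backbone's variant vs that backbone alone."""
    table = TOTAL_MAEF if metric == "maef" else TOTAL_MDAEF
    i = BACKBONES.index(backbone)
    return ablation_reduction([table["alone"][i]], [table[variant][i]])
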