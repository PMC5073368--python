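"""Bruise ratio index: per-berry bruise quantification and calling.

The bruise ratio index of a berry is the fraction of its fruit pixels
classified as bruised, with calyx-excluded pixels removed from both
numerator and denominator.  When a berry is imaged from both the stem
and calyx sides, the index is the arithmetic mean of the two per-side
ratios.  A berry whose index exceeds 0.2 (20% bruised area, the
conventional grading cut-off) is called bruised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BRUISED_CODE, HEALTHY_CODE, ClassifiedImage

__all__ = [
    "BruiseReport",
    "bruise_ratio",
    "two_side_ratio",
    "call_bruised",
    "count_bruised",
    "build_report",
    "match_berries_by_rank",
    "BRUISE_THRESHOLD",
]

log = logging.getLogger(__name__)

BRUISE_THRESHOLD = 0.2
"""Default bruised-fruit calling threshold on the ratio index."""


@dataclass
class BruiseReport:
    """Quantification record for one berry (or one matched berry pair)."""

    berry_id: int
    side: str  # stem | calyx | single
    bruise_ratio: float
    bruised: bool
    firmness: float | None = None
    human_assessment: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bruise_ratio <= 1.0:
            raise ValueError(f"bruise_ratio {self.bruise_ratio} outside [0, 1]")


def bruise_ratio(classified: ClassifiedImage, berry_id: int) -> float:
    """Bruised / (bruised + healthy) pixel count for one berry.

    Calyx-excluded pixels count toward neither the numerator nor the
    denominator, so the index is unaffected by the excluded disc size.
    """
    mask = classified.labelmap.berry_mask(berry_id)
    codes = classified.classes[mask]
    n_bruised = int(np.sum(codes == BRUISED_CODE))
    n_healthy = int(np.sum(codes == HEALTHY_CODE))
    countable = n_bruised + n_healthy
    if countable == 0:
        raise ValueError(f"berry {berry_id} has no countable (non-excluded) pixels")
    return n_bruised / countable


def two_side_ratio(stem_ratio: float, calyx_ratio: float) -> float:
    """Whole-fruit index: mean of the stem-side and calyx-side ratios."""
    for name, r in (("stem", stem_ratio), ("calyx", calyx_ratio)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} ratio {r} outside [0, 1]")
    return (stem_ratio + calyx_ratio) / 2.0


def call_bruised(ratio: float, threshold: float = BRUISE_THRESHOLD) -> bool:
    """True iff the index strictly exceeds the threshold."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    return ratio > threshold


def count_bruised(
    ratios: "list[float] | np.ndarray", threshold: float = BRUISE_THRESHOLD
) -> int:
    """Number of bruised calls in one treatment-replicate group."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        log.warning("count_bruised: empty replicate group")
        return 0
    return int(np.sum(ratios > threshold))


def match_berries_by_rank(
    stem: ClassifiedImage, calyx: ClassifiedImage
) -> list[tuple[int, int]]:
    """Pair berries across the two views by raster rank of their centers.

    The same physical tray is imaged from both sides, so berries appear
    in the same row-major layout; sorting centers in row-major order and
    pairing by rank recovers the correspondence.
    """
    def ranked(ci: ClassifiedImage) -> list[int]:
        return sorted(ci.labelmap.centers, key=lambda b: ci.labelmap.centers[b])

    ids_s, ids_c = ranked(stem), ranked(calyx)
    if len(ids_s) != len(ids_c):
        raise ValueError(
            f"stem view has {len(ids_s)} berries but calyx view has {len(ids_c)}"
        )
    return list(zip(ids_s, ids_c))


def build_report(
    stem: ClassifiedImage,
    calyx: ClassifiedImage | None = None,
    threshold: float = BRUISE_THRESHOLD,
    firmness: dict[int, float] | None = None,
    human: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-berry bruise report as a DataFrame.

    With a single view, each berry yields one ``side='single'`` row.
    With both views, berries are rank-matched and each pair yields one
    row holding the two-side mean index; ``berry_id`` is the stem-view
    id.  Optional firmness (N/mm) and human-assessment fractions are
    joined on stem-view berry id.
    """
    rows = []
    if calyx is None:
        for bid in stem.labelmap.berry_ids():
            r = bruise_ratio(stem, bid)
            rows.append((bid, "single", r))
    else:
        for bid_s, bid_c in match_berries_by_rank(stem, calyx):
            r = two_side_ratio(bruise_ratio(stem, bid_s), bruise_ratio(calyx, bid_c))
            rows.append((bid_s, "both", r))
    df = pd.DataFrame(rows, columns=["berry_id", "side", "bruise_ratio"])
    df["bruised"] = df["bruise_ratio"] > threshold
    df["firmness"] = df["berry_id"].map(firmness) if firmness else np.nan
    df["human_assessment"] = df["berry_id"].map(human) if human else np.nan
    return df
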