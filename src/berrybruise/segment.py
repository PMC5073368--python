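"""Automatic berry segmentation and calyx-end exclusion.

Berries sit on a dark background and reflect strongly near 1075 nm, so
a global DN threshold on that band separates fruit from background.
Morphological cleanup fills interior holes (the dark calyx end punches
a hole in the raw mask) and drops small noise specks; connected
components then identify individual berries.

The calyx end reflects as little NIR light as bruised tissue and would
otherwise be misclassified, so a fixed-radius disc around each berry
center is excluded from classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "LabelMap",
    "threshold_mask",
    "refine_mask",
    "label_components",
    "calyx_exclusion_mask",
]

log = logging.getLogger(__name__)


@dataclass
class LabelMap:
    """Integer raster assigning pixels to berries.

    ``labels`` uses 0 for background and 1..N for berries; ``centers``
    maps each berry id to its component centroid rounded to the nearest
    pixel (row, col).
    """

    labels: np.ndarray
    centers: dict[int, tuple[int, int]]

    @property
    def n_berries(self) -> int:
        return len(self.centers)

    def berry_ids(self) -> list[int]:
        return sorted(self.centers)

    def berry_mask(self, berry_id: int) -> np.ndarray:
        if berry_id not in self.centers:
            raise KeyError(f"no berry with id {berry_id}")
        return self.labels == berry_id


def threshold_mask(band_image: np.ndarray, level_dn: float) -> np.ndarray:
    """Foreground mask: pixels strictly brighter than ``level_dn``.

    Operates on the raw DN grayscale at the segmentation band (1075 nm
    by convention; published levels such as 737 and 942 are on the
    0--4095 DN scale).  Strict ``>`` is the documented convention.
    """
    return np.asarray(band_image) > level_dn


def refine_mask(mask: np.ndarray, min_object_px: int = 50) -> np.ndarray:
    """Fill interior holes and remove components below ``min_object_px``."""
    mask = np.asarray(mask, dtype=bool)
    filled = ndi.binary_fill_holes(mask)
    if min_object_px > 0:
        labels, n = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            keep = sizes >= min_object_px  # strictly smaller components dropped
            filled = keep[labels]
    return filled


def label_components(mask: np.ndarray, connectivity: int = 2) -> LabelMap:
    """Label connected foreground components (8-connectivity default).

    Component centers are pixel-rounded centroids.  An empty mask is a
    valid (if suspicious) result and only logs a warning.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=connectivity)
    centers: dict[int, tuple[int, int]] = {}
    for region in measure.regionprops(labels):
        r, c = region.centroid
        centers[int(region.label)] = (int(round(r)), int(round(c)))
    if not centers:
        log.warning("label_components: no foreground components found")
    return LabelMap(labels.astype(np.int32), centers)


def calyx_exclusion_mask(labelmap: LabelMap, radius_px: int = 5) -> np.ndarray:
    """Closed disc of ``radius_px`` around each berry center, clipped to the berry.

    Pixels with squared distance to the center ``<= radius**2`` and
    belonging to that berry are marked for exclusion from tissue
    classification.
    """
    labels = labelmap.labels
    out = np.zeros(labels.shape, dtype=bool)
    r2 = radius_px * radius_px
    nrows, ncols = labels.shape
    for berry_id, (cr, cc) in labelmap.centers.items():
        r0, r1 = max(0, cr - radius_px), min(nrows, cr + radius_px + 1)
        c0, c1 = max(0, cc - radius_px), min(ncols, cc + radius_px + 1)
        rr, cc_grid = np.mgrid[r0:r1, c0:c1]
        disc = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= r2
        out[r0:r1, c0:c1] |= disc & (labels[r0:r1, c0:c1] == berry_id)
    return out
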