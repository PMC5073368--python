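"""Flat-field reflectance calibration.

Raw digital numbers depend on illumination, integration time and
pixel-to-pixel detector sensitivity.  Imaging a near-perfect white
reference panel and a lens-capped dark frame lets all of that cancel:

    R = (S - D) / (W - D)

per pixel and band.  Pixels where the white and dark references agree
carry no calibration information and are flagged invalid (set to 0).
"""

from __future__ import annotations

import logging

import numpy as np

from .cube import HyperCube

__all__ = ["flat_field_correct"]

log = logging.getLogger(__name__)


def flat_field_correct(
    raw: HyperCube,
    white: HyperCube,
    dark: HyperCube,
    clip_max: float = 2.0,
) -> HyperCube:
    """Convert a raw DN cube to reflectance against white/dark references.

    Parameters
    ----------
    raw, white, dark
        Sample, white-panel and dark-current cubes of identical shape
        and wavelength grid.
    clip_max
        Upper clip for the reflectance ratio; glints off specular
        surfaces can exceed 1 and are capped here rather than left to
        dominate later statistics.

    Returns
    -------
    HyperCube
        Float32 reflectance cube, values in ``[0, clip_max]``,
        ``kind='reflectance'``.
    """
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError("raw, white and dark cubes must share one shape")
    if not (
        np.array_equal(raw.grid.values, white.grid.values)
        and np.array_equal(raw.grid.values, dark.grid.values)
    ):
        raise ValueError("raw, white and dark cubes must share one wavelength grid")
    s = raw.data.astype(np.float64)
    w = white.data.astype(np.float64)
    d = dark.data.astype(np.float64)
    denom = w - d
    invalid = denom <= 0
    n_bad = int(invalid.sum())
    if n_bad:
        log.warning("flat-field: %d pixel/band cells have white <= dark; set to 0", n_bad)
        denom[invalid] = 1.0
    refl = (s - d) / denom
    refl[invalid] = 0.0
    np.clip(refl, 0.0, clip_max, out=refl)
    return HyperCube(refl.astype(np.float32), raw.grid, kind="reflectance")
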