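"""Mask, label and classified-image raster I/O.

Binary masks travel as single-band 8-bit images (0 background, 255
foreground), label maps as 16-bit TIFF, and classified images as
paletted PNGs (black background, green healthy, red bruised, gray
excluded) alongside a raw label TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .classify import BACKGROUND, BRUISED_CODE, EXCLUDED_CODE, HEALTHY_CODE

__all__ = [
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "write_classified_png",
]

_PALETTE = {
    BACKGROUND: (0, 0, 0),
    HEALTHY_CODE: (0, 180, 0),
    BRUISED_CODE: (220, 0, 0),
    EXCLUDED_CODE: (128, 128, 128),
}


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-band 8-bit mask; any nonzero pixel is foreground."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-band mask")
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def read_labels(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-band label raster")
    return arr.astype(np.int32)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def write_classified_png(classes: np.ndarray, path: str | Path) -> None:
    """Paletted RGB rendering of a classified raster."""
    rgb = np.zeros((*classes.shape, 3), dtype=np.uint8)
    for code, color in _PALETTE.items():
        rgb[classes == code] = color
    Image.fromarray(rgb, mode="RGB").save(path)
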