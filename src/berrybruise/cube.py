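"""Hyperspectral cubes, wavelength grids and ENVI container I/O.

A cube is a plain ``(rows, cols, bands)`` numpy raster together with the
band-center wavelengths.  Raw camera frames are 12-bit digital numbers
(DN, 0--4095); after flat-field calibration the cube holds dimensionless
reflectance.  The on-disk container is the de-facto ENVI pair: an ASCII
header describing dimensions, interleave and wavelengths, plus a flat
binary image file.  Interleave (BIL/BSQ/BIP) is purely an I/O concern;
in memory the layout is always row-major ``(row, col, band)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "make_wavelength_grid",
    "band_index",
    "read_envi",
    "write_envi",
]

DN_MAX = 4095
"""Full scale of the camera's 12-bit digitizer."""

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v).name: k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced band-center wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid needs at least two bands")
        steps = np.diff(vals)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("wavelength spacing must be uniform")
        object.__setattr__(self, "values", vals)

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def end_nm(self) -> float:
        return float(self.values[-1])

    @property
    def step_nm(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)


def make_wavelength_grid(start_nm: float, end_nm: float, step_nm: float) -> WavelengthGrid:
    """Build the band grid from a closed range and interval.

    The instrument modelled here covers 950--1650 nm in 5 nm steps,
    i.e. 141 bands; both endpoints are band centers, so the range must
    be an exact multiple of the step.
    """
    if end_nm <= start_nm:
        raise ValueError(f"end_nm ({end_nm}) must exceed start_nm ({start_nm})")
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    n_steps = (end_nm - start_nm) / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"range {start_nm}-{end_nm} nm is not divisible by step {step_nm} nm"
        )
    n = int(round(n_steps)) + 1
    return WavelengthGrid(start_nm + step_nm * np.arange(n))


def band_index(grid: WavelengthGrid, wavelength_nm: float) -> int:
    """Index of the band whose center is nearest ``wavelength_nm``.

    Ties (a wavelength exactly between two centers) resolve to the lower
    index.  Wavelengths further than half a step outside the grid are
    rejected rather than clamped.
    """
    half = grid.step_nm / 2.0
    if wavelength_nm < grid.start_nm - half or wavelength_nm > grid.end_nm + half:
        raise ValueError(
            f"{wavelength_nm} nm outside grid {grid.start_nm}-{grid.end_nm} nm"
        )
    offset = (wavelength_nm - grid.start_nm) / grid.step_nm
    # round half toward lower index
    idx = int(np.floor(offset + 0.5))
    if offset + 0.5 == np.floor(offset + 0.5) and idx > 0:
        idx -= 1
    return int(np.clip(idx, 0, len(grid) - 1))


@dataclass
class HyperCube:
    """A ``(rows, cols, bands)`` raster with its wavelength grid.

    ``kind`` records where the cube sits in the calibration chain:
    ``raw``, ``white_ref`` and ``dark_ref`` are DN cubes; ``reflectance``
    is the flat-field corrected result.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"

    _KINDS = ("raw", "white_ref", "dark_ref", "reflectance")

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.kind != "reflectance":
            if self.data.min() < 0 or self.data.max() > DN_MAX:
                raise ValueError(f"DN cube values must lie in [0, {DN_MAX}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Grayscale image at the band nearest the given wavelength."""
        return self.data[:, :, band_index(self.grid, wavelength_nm)]


def _format_header(cube: HyperCube, interleave: str) -> str:
    rows, cols, bands = cube.shape
    code = _ENVI_CODES[cube.data.dtype.name]
    wl = ", ".join(f"{w:g}" for w in cube.grid.values)
    return (
        "ENVI\n"
        "description = {berrybruise hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )


def _parse_header(text: str) -> dict:
    # collapse multi-line { ... } blocks before splitting into fields
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bil") -> Path:
    """Write ``<path>.hdr`` + ``<path>.img``; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if cube.data.dtype.name not in _ENVI_CODES:
        raise ValueError(f"unsupported dtype {cube.data.dtype}")
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".hdr" else path
    hdr, img = base.with_suffix(".hdr"), base.with_suffix(".img")
    # memory order per interleave: bsq=(band,row,col) bil=(row,band,col) bip=(row,col,band)
    if interleave == "bip":
        arr = cube.data
    elif interleave == "bil":
        arr = np.transpose(cube.data, (0, 2, 1))
    else:
        arr = np.transpose(cube.data, (2, 0, 1))
    hdr.write_text(_format_header(cube, interleave))
    np.ascontiguousarray(arr).tofile(img)
    return hdr


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/binary pair back into a :class:`HyperCube`."""
    hdr = Path(header_path)
    fields = _parse_header(hdr.read_text())
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise ValueError(f"ENVI header missing {key!r}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength block")
    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unsupported interleave {fields['interleave']!r}")
    wl = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{} ").split(",") if tok.strip()]
    )
    if wl.size != bands:
        raise ValueError(f"header lists {wl.size} wavelengths but {bands} bands")
    img = hdr.with_suffix(".img")
    raw = np.fromfile(img, dtype=_ENVI_DTYPES[code])
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"{img} holds {raw.size} values, expected {rows * cols * bands}"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
    else:
        data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    kind = fields.get("cube kind", "raw")
    if kind not in HyperCube._KINDS:
        kind = "reflectance" if code in (4, 5) else "raw"
    return HyperCube(np.ascontiguousarray(data), WavelengthGrid(wl), kind=kind)
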