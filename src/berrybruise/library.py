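"""Pixel-spectrum libraries: extraction, normalization, balancing, merging.

A spectral library is a labeled matrix of single-pixel reflectance
spectra (healthy vs bruised tissue) drawn from regions of interest.
Normalization removes multiplicative illumination differences between
acquisitions so that libraries from different experiments are
compatible; balancing equalizes class counts before classifier
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import HyperCube, WavelengthGrid

__all__ = [
    "SpectralLibrary",
    "extract_roi_spectra",
    "normalize_spectrum",
    "normalize_library",
    "balance_library",
    "merge_libraries",
    "HEALTHY",
    "BRUISED",
]

HEALTHY = "healthy"
BRUISED = "bruised"


@dataclass
class SpectralLibrary:
    """N x B matrix of pixel spectra with per-row class labels."""

    spectra: np.ndarray
    class_labels: np.ndarray  # array of str, one of {healthy, bruised}
    wavelengths: np.ndarray
    source_tag: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.shape[0] != self.class_labels.size:
            raise ValueError("one class label required per spectrum row")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra width must equal number of wavelengths")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("library spectra must be finite")
        bad = set(self.class_labels) - {HEALTHY, BRUISED}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.class_labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, rows: np.ndarray) -> "SpectralLibrary":
        return replace(
            self, spectra=self.spectra[rows], class_labels=self.class_labels[rows]
        )

    # --- CSV serialization: class, source, one column per wavelength ---
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.spectra, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "source", self.source_tag)
        df.insert(0, "class", self.class_labels.astype(str))
        df.insert(0, "normalized", self.normalized)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralLibrary":
        df = pd.read_csv(path)
        meta = ["normalized", "class", "source"]
        wl = np.array([float(c) for c in df.columns if c not in meta])
        return cls(
            spectra=df.drop(columns=meta).to_numpy(float),
            class_labels=df["class"].to_numpy(),
            wavelengths=wl,
            source_tag=str(df["source"].iloc[0]) if len(df) else "",
            normalized=bool(df["normalized"].iloc[0]) if len(df) else False,
        )


def extract_roi_spectra(
    cube: HyperCube, roi_mask: np.ndarray, class_label: str, source_tag: str = ""
) -> SpectralLibrary:
    """One library row per foreground ROI pixel, in raster-scan order."""
    if cube.kind != "reflectance":
        raise ValueError("extract_roi_spectra expects a calibrated reflectance cube")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != cube.shape[:2]:
        raise ValueError(
            f"ROI mask shape {roi_mask.shape} does not match cube {cube.shape[:2]}"
        )
    if not roi_mask.any():
        raise ValueError("ROI mask selects no pixels")
    spectra = cube.data[roi_mask]  # raster order: rows scanned top-to-bottom
    labels = np.full(spectra.shape[0], class_label, dtype=object)
    return SpectralLibrary(spectra, labels, cube.grid.values, source_tag=source_tag)


def normalize_spectrum(spectrum: np.ndarray, method: str = "mean") -> np.ndarray:
    """Normalize one spectrum (or a stack of them, rows = spectra).

    ``mean`` divides each spectrum by its own band average, removing
    multiplicative illumination scaling while preserving shape; the
    result has mean 1.  ``snv`` (standard normal variate) centers each
    spectrum and scales to unit variance.
    """
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if method == "mean":
        m = x.mean(axis=1, keepdims=True)
        if np.any(m <= 0):
            raise ValueError("cannot mean-normalize a spectrum with mean <= 0")
        out = x / m
    elif method == "snv":
        m = x.mean(axis=1, keepdims=True)
        s = x.std(axis=1, keepdims=True)
        if np.any(s == 0):
            raise ValueError("cannot SNV-normalize a constant spectrum")
        out = (x - m) / s
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out[0] if squeeze else out


def normalize_library(lib: SpectralLibrary, method: str = "mean") -> SpectralLibrary:
    """Row-wise normalization of a whole library."""
    return replace(lib, spectra=normalize_spectrum(lib.spectra, method), normalized=True)


def balance_library(lib: SpectralLibrary, seed: int = 17) -> SpectralLibrary:
    """Equalize class counts by subsampling the majority class.

    The minority class is kept whole; the majority class is sampled
    uniformly without replacement under ``seed``.  Row order within the
    retained set is preserved.
    """
    counts = lib.class_counts()
    if set(counts) != {HEALTHY, BRUISED}:
        raise ValueError(f"both classes required to balance, found {sorted(counts)}")
    n_keep = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(lib), dtype=bool)
    for label in (HEALTHY, BRUISED):
        idx = np.flatnonzero(lib.class_labels.astype(str) == label)
        if idx.size > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep[idx] = True
    return lib.subset(np.flatnonzero(keep))


def merge_libraries(a: SpectralLibrary, b: SpectralLibrary) -> SpectralLibrary:
    """Row-wise concatenation of two libraries on the same band grid."""
    if len(b) == 0:
        return a
    if len(a) == 0:
        return b
    if a.wavelengths.size != b.wavelengths.size or not np.allclose(
        a.wavelengths, b.wavelengths
    ):
        raise ValueError("libraries are on different wavelength grids")
    if a.normalized != b.normalized:
        raise ValueError("cannot merge normalized with unnormalized library")
    tag = a.source_tag if a.source_tag == b.source_tag else f"{a.source_tag}+{b.source_tag}"
    return SpectralLibrary(
        np.vstack([a.spectra, b.spectra]),
        np.concatenate([a.class_labels, b.class_labels]),
        a.wavelengths,
        source_tag=tag,
        normalized=a.normalized,
    )
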