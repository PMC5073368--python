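"""Synthetic hyperspectral phantoms with known ground truth.

No public hyperspectral bruise datasets exist, so every pipeline stage
is exercised on generated scenes that emulate the imaging conditions:
trays of near-spherical berries (rendered as discs) on a dark
background, NIR reflectance spectra with water-absorption dips near
980, 1200 and 1470 nm, a post-1470 nm upturn present only in healthy
tissue, a dark calyx spot at each berry center, smooth illumination
non-uniformity, and 12-bit sensor noise.  White and dark reference
cubes are generated consistently with the illumination field so that
flat-field calibration recovers the underlying reflectance.

Ground truth (berry masks, bruise masks, true bruise fractions, true
firmness) is returned alongside each scene, which is what makes
acceptance-style end-to-end checks possible.

All randomness flows from a single seed through ``SeedSequence``
spawning, one child stream per concern (geometry, fractions, spectra,
sensor, firmness), so scenes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .cube import HyperCube, WavelengthGrid, make_wavelength_grid
from .firmness import FirmnessCurve

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "SceneBundle",
    "healthy_spectrum",
    "bruised_spectrum",
    "calyx_spectrum",
    "make_scene",
    "make_force_curve",
    "simulate_human_assessment",
    "DEFAULT_TREATMENTS",
]

DEFAULT_TREATMENTS: dict[str, tuple[float, float]] = {
    # uniform ranges of true bruise fraction per berry, mirroring a
    # drop-height design: higher drops onto harder surfaces bruise more
    "control": (0.0, 0.0),
    "pad120": (0.08, 0.25),
    "steel60": (0.25, 0.45),
    "steel120": (0.45, 0.70),
    "fully_bruised": (0.92, 1.0),
}


@dataclass
class PhantomConfig:
    """Generator settings; defaults define the reference study conditions.

    ``spectral_noise_sd`` is additive per-pixel per-band reflectance
    noise on tissue spectra; its default was calibrated once so that
    10-fold CV accuracy of the default SVM on default-noise libraries
    falls in the mid-90s, the regime the method is designed for.
    ``pixel_scale_sd`` is a per-pixel multiplicative brightness jitter
    (biological + illumination micro-variation) that normalization is
    expected to remove.
    """

    rows: int = 280
    cols: int = 280
    n_berries: int = 25
    radius_range: tuple[int, int] = (18, 22)
    treatments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENTS)
    )
    bruise_shape: str = "cap"  # cap (stem-side chord) | blob (offset disc)
    spectral_noise_sd: float = 0.12
    pixel_scale_sd: float = 0.05
    illumination_amplitude: float = 0.15
    illumination_scale: float = 1.0  # global lamp-brightness factor between datasets
    dn_max: int = 4095
    dark_dn: float = 100.0
    gain: float = 3300.0
    dn_noise_sd: float = 5.0
    calyx_spot_radius: int = 4
    calyx_exclusion_radius: int = 5
    background_reflectance: float = 0.02
    firmness_intercept: float = 2.9  # N/mm of an unbruised berry
    firmness_slope: float = 1.6  # N/mm lost per unit bruise fraction
    firmness_noise_sd: float = 0.08  # ~5% of the firmness range
    assessment_noise_sd: float = 0.08
    grid_start_nm: float = 950.0
    grid_end_nm: float = 1650.0
    grid_step_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.spectral_noise_sd < 0 or self.dn_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for name, (lo, hi) in self.treatments.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"treatment {name!r} fraction range outside [0, 1]")
        if self.bruise_shape not in ("cap", "blob"):
            raise ValueError("bruise_shape must be 'cap' or 'blob'")

    def grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.grid_start_nm, self.grid_end_nm, self.grid_step_nm)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((wl - center) ** 2) / (2.0 * width**2))


def healthy_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Healthy-tissue reflectance: water dips, recovery after 1470 nm."""
    wl = grid.values
    base = 0.70 - 0.00005 * (wl - 950.0)
    r = (
        base
        - 0.07 * _gauss(wl, 980.0, 22.0)
        - 0.11 * _gauss(wl, 1200.0, 40.0)
        - 0.34 * _gauss(wl, 1470.0, 68.0)
    )
    return np.clip(r, 0.0, 1.0)


def bruised_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Bruised-tissue reflectance: more free water, darker, flat past 1470 nm.

    Free water released by damaged cells deepens the absorption dips and
    lowers overall reflectance; past the 1470 nm global minimum the
    spectrum stays flat instead of recovering.
    """
    wl = grid.values
    base = 0.54 - 0.00005 * (wl - 950.0)
    r = (
        base
        - 0.09 * _gauss(wl, 980.0, 22.0)
        - 0.15 * _gauss(wl, 1200.0, 40.0)
        - 0.30 * _gauss(wl, 1470.0, 68.0)
    )
    # no post-minimum upturn: clamp the tail to the 1470 nm level with a
    # barely-positive drift (flat to within 0.02)
    i_min = int(np.argmin(np.abs(wl - 1470.0)))
    tail = wl > wl[i_min]
    r[tail] = r[i_min] + 0.00005 * (wl[tail] - wl[i_min])
    return np.clip(r, 0.0, 1.0)


def calyx_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Calyx-end reflectance: uniformly dark across all bands."""
    return np.full(len(grid), 0.08)


@dataclass
class PhantomTruth:
    """Ground truth for one generated scene."""

    labels: np.ndarray  # int raster, 0 background, 1..N berries
    bruise_mask: np.ndarray  # bool raster, true bruised-tissue pixels
    calyx_mask: np.ndarray  # bool raster, dark calyx spots
    centers: dict[int, tuple[int, int]]
    fractions: dict[int, float]  # true bruise fraction over countable pixels
    firmness: dict[int, float]  # N/mm
    treatment: str

    def countable_mask(self, berry_id: int, exclusion_radius: int = 5) -> np.ndarray:
        """Berry pixels outside the calyx exclusion disc."""
        cr, cc = self.centers[berry_id]
        rr, cc_grid = np.mgrid[0 : self.labels.shape[0], 0 : self.labels.shape[1]]
        disc = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= exclusion_radius**2
        return (self.labels == berry_id) & ~disc


@dataclass
class SceneBundle:
    """A generated acquisition: raw + references + ground truth."""

    raw: HyperCube
    white: HyperCube
    dark: HyperCube
    truth: PhantomTruth


def _place_berries(cfg: PhantomConfig, rng: np.random.Generator):
    """Jittered grid layout; guarantees non-overlap by construction."""
    side = int(np.ceil(np.sqrt(cfg.n_berries)))
    r_max = cfg.radius_range[1]
    pitch = 2 * r_max + 12
    # jittered centers sit at pitch/2 from each cell edge, so side*pitch
    # already leaves >= r_max + 3 margin at the borders
    needed = side * pitch
    if cfg.rows < needed or cfg.cols < needed:
        raise ValueError(
            f"scene {cfg.rows}x{cfg.cols} too small for {cfg.n_berries} berries "
            f"of radius <= {r_max} (needs >= {needed} px per side)"
        )
    row_off = (cfg.rows - side * pitch) // 2
    col_off = (cfg.cols - side * pitch) // 2
    berries = []
    for i in range(cfg.n_berries):
        gr, gc = divmod(i, side)
        jr, jc = rng.integers(-3, 4, size=2)
        cr = row_off + gr * pitch + pitch // 2 + int(jr)
        cc = col_off + gc * pitch + pitch // 2 + int(jc)
        radius = int(rng.integers(cfg.radius_range[0], cfg.radius_range[1] + 1))
        berries.append((cr, cc, radius))
    return berries


def _bruise_pixels(
    cfg: PhantomConfig,
    countable_rc: np.ndarray,
    fraction: float,
    center: tuple[int, int],
    radius: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Select bruised pixels among countable ones, hitting ``fraction`` exactly.

    ``cap`` grows a chord-bounded cap from the stem (left) side, the
    side the impact hits; ``blob`` grows a disc around an off-center
    seed, which can miss the equatorial slice row entirely.
    """
    n = countable_rc.shape[0]
    k = int(round(fraction * n))
    if k == 0:
        return np.zeros(0, dtype=int)
    if cfg.bruise_shape == "cap":
        order = np.lexsort((countable_rc[:, 0], countable_rc[:, 1]))  # by col, then row
    else:
        ang = rng.uniform(0, 2 * np.pi)
        seed_r = center[0] + 0.6 * radius * np.sin(ang)
        seed_c = center[1] + 0.6 * radius * np.cos(ang)
        d2 = (countable_rc[:, 0] - seed_r) ** 2 + (countable_rc[:, 1] - seed_c) ** 2
        order = np.argsort(d2)
    return order[:k]


def make_scene(
    cfg: PhantomConfig, treatment: str | float, seed: int
) -> SceneBundle:
    """Generate one acquisition (raw/white/dark DN cubes) with ground truth.

    ``treatment`` is either a named entry of ``cfg.treatments`` or a
    float applied as the exact target fraction for every berry.
    """
    if isinstance(treatment, str):
        if treatment not in cfg.treatments:
            raise KeyError(f"unknown treatment {treatment!r}")
        frac_lo, frac_hi = cfg.treatments[treatment]
        treat_name = treatment
    else:
        frac_lo = frac_hi = float(treatment)
        treat_name = f"fraction={treatment:g}"
        if not 0.0 <= frac_lo <= 1.0:
            raise ValueError("treatment fraction outside [0, 1]")

    grid = cfg.grid()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    rng_geom, rng_frac, rng_spec, rng_sensor, rng_firm = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    labels = np.zeros((cfg.rows, cfg.cols), dtype=np.int32)
    bruise_mask = np.zeros_like(labels, dtype=bool)
    calyx_mask = np.zeros_like(labels, dtype=bool)
    centers: dict[int, tuple[int, int]] = {}
    fractions: dict[int, float] = {}
    firmness: dict[int, float] = {}

    rr_full, cc_full = np.mgrid[0 : cfg.rows, 0 : cfg.cols]
    for bid, (cr, cc, radius) in enumerate(_place_berries(cfg, rng_geom), start=1):
        disc = (rr_full - cr) ** 2 + (cc_full - cc) ** 2 <= radius**2
        labels[disc] = bid
        centers[bid] = (cr, cc)
        spot = (rr_full - cr) ** 2 + (cc_full - cc) ** 2 <= cfg.calyx_spot_radius**2
        calyx_mask |= spot & disc

        excl = (rr_full - cr) ** 2 + (cc_full - cc) ** 2 <= cfg.calyx_exclusion_radius**2
        countable = disc & ~excl
        rc = np.argwhere(countable)
        target = rng_frac.uniform(frac_lo, frac_hi)
        chosen = _bruise_pixels(cfg, rc, target, (cr, cc), radius, rng_frac)
        if chosen.size:
            bruise_mask[rc[chosen, 0], rc[chosen, 1]] = True
        fractions[bid] = chosen.size / rc.shape[0]
        f = (
            cfg.firmness_intercept
            - cfg.firmness_slope * fractions[bid]
            + rng_firm.normal(0.0, cfg.firmness_noise_sd)
        )
        firmness[bid] = float(max(f, 0.3))

    truth = PhantomTruth(
        labels, bruise_mask, calyx_mask, centers, fractions, firmness, treat_name
    )

    # --- reflectance scene ---------------------------------------------
    spectra = np.stack(
        [
            np.full(len(grid), cfg.background_reflectance),  # 0 background
            healthy_spectrum(grid),  # 1 healthy tissue
            bruised_spectrum(grid),  # 2 bruised tissue
            calyx_spectrum(grid),  # 3 calyx spot
        ]
    )
    class_map = np.zeros_like(labels, dtype=np.int8)
    class_map[labels > 0] = 1
    class_map[bruise_mask] = 2
    class_map[calyx_mask] = 3
    refl = spectra.astype(np.float32)[class_map]  # rows x cols x bands

    tissue = labels > 0
    scale = rng_spec.normal(1.0, cfg.pixel_scale_sd, size=labels.shape)
    refl[tissue] *= np.clip(scale[tissue], 0.5, 1.5).astype(np.float32)[:, None]
    noise = cfg.spectral_noise_sd * rng_spec.standard_normal(
        refl[tissue].shape, dtype=np.float32
    )
    refl[tissue] = np.clip(refl[tissue] + noise, 0.0, 1.0)

    # --- illumination field and DN conversion --------------------------
    gr = (rr_full / max(cfg.rows - 1, 1) - 0.5) + 0.6 * (
        cc_full / max(cfg.cols - 1, 1) - 0.5
    )
    blob = np.exp(
        -(
            (rr_full - cfg.rows / 2.0) ** 2 / (2 * (0.6 * cfg.rows) ** 2)
            + (cc_full - cfg.cols / 2.0) ** 2 / (2 * (0.6 * cfg.cols) ** 2)
        )
    )
    fld = gr + (blob - blob.mean())
    fld = fld / np.max(np.abs(fld))
    illum = cfg.illumination_scale * (1.0 + cfg.illumination_amplitude * fld)

    illum32 = illum.astype(np.float32)

    def to_dn(reflectance: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        dn = (
            np.float32(cfg.dark_dn)
            + illum32[:, :, None] * reflectance * np.float32(cfg.gain)
            + np.float32(cfg.dn_noise_sd)
            * rng.standard_normal(reflectance.shape, dtype=np.float32)
        )
        return np.clip(np.round(dn), 0, cfg.dn_max).astype(np.uint16)

    raw = HyperCube(to_dn(refl, rng_sensor), grid, kind="raw")
    white = HyperCube(
        to_dn(np.full_like(refl, 0.99, dtype=np.float32), rng_sensor),
        grid,
        kind="white_ref",
    )
    dark_dn = np.clip(
        np.round(
            cfg.dark_dn
            + cfg.dn_noise_sd * rng_sensor.standard_normal(refl.shape, dtype=np.float32)
        ),
        0,
        cfg.dn_max,
    ).astype(np.uint16)
    dark = HyperCube(dark_dn, grid, kind="dark_ref")
    return SceneBundle(raw, white, dark, truth)


def make_library(
    cfg: PhantomConfig, n_per_class: int, seed: int, source_tag: str = "phantom"
):
    """Sample a labeled pixel-spectrum library directly from the tissue models.

    Each row is a class spectrum with the generator's per-pixel
    brightness jitter and additive band noise — the same sampling model
    the scenes use, but with exact class labels (no region-of-interest
    contamination).  Useful for classifier calibration studies.
    """
    from .library import BRUISED, HEALTHY, SpectralLibrary

    grid = cfg.grid()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 99]))
    blocks, labels = [], []
    for spec, label in ((healthy_spectrum(grid), HEALTHY), (bruised_spectrum(grid), BRUISED)):
        scale = np.clip(rng.normal(1.0, cfg.pixel_scale_sd, (n_per_class, 1)), 0.5, 1.5)
        X = np.clip(
            spec * scale + rng.normal(0.0, cfg.spectral_noise_sd, (n_per_class, len(grid))),
            0.0,
            1.0,
        )
        blocks.append(X)
        labels += [label] * n_per_class
    return SpectralLibrary(
        np.vstack(blocks), np.array(labels, dtype=object), grid.values, source_tag
    )


def make_force_curve(
    true_slope: float,
    noise_sd: float = 0.01,
    seed: int = 0,
    total_mm: float = 3.0,
    step_mm: float = 0.01,
    nonlinear_ends: bool = False,
) -> FirmnessCurve:
    """Force/deformation curve of a parallel-plate compression test.

    Linear with the given slope inside the 0.5--2.5 mm fitting window;
    ``nonlinear_ends`` adds a contact toe below 0.5 mm and a stiffening
    plateau beyond 2.5 mm, both continuous at the window edges.
    """
    if true_slope <= 0:
        raise ValueError("true_slope must be positive")
    d = np.arange(0.0, total_mm + step_mm / 2, step_mm)
    f = true_slope * d
    if nonlinear_ends:
        toe = d < 0.5
        f[toe] = true_slope * 0.5 * (d[toe] / 0.5) ** 2
        plateau = d > 2.5
        f[plateau] = true_slope * 2.5 + 1.6 * true_slope * (d[plateau] - 2.5)
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, size=d.shape)
    return FirmnessCurve(d, f)


def simulate_human_assessment(
    truth: PhantomTruth,
    noise_sd: float = 0.08,
    seed: int = 0,
) -> dict[int, float]:
    """Grader's bruise fraction on each berry's equatorial slice row.

    The grader sees only the central cross-section: the assessment is
    the bruised/total pixel ratio along the berry's center row, plus
    truncated Gaussian grading noise.  The calyx region is not graded
    (it discolors for reasons other than bruising), matching the
    index's exclusion convention.  Bruises that never reach the slice
    row are invisible to the grader — the known failure mode of
    slice-based inspection.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for bid, (cr, _cc) in sorted(truth.centers.items()):
        row_mask = truth.countable_mask(bid)[cr, :]
        total = int(row_mask.sum())
        if total == 0:  # degenerate berry; grade as unreadable zero
            out[bid] = 0.0
            continue
        bruised = int((truth.bruise_mask[cr, :] & row_mask).sum())
        val = bruised / total + rng.normal(0.0, noise_sd)
        out[bid] = float(np.clip(val, 0.0, 1.0))
    return out
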