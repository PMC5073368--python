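# Methods

## Reflectance model and calibration

Raw frames are 12-bit digital numbers (DN, 0–4095). Reflectance is
computed per pixel and band as R = (S − D)/(W − D) from a white-panel
cube W and a dark-current cube D of the same shape and wavelength grid.
Cells with W ≤ D carry no calibration information; they are set to 0
and counted in a log message rather than propagated as NaN/Inf. The
ratio is clipped to [0, `clip_max`] (default 2.0) so specular glints
cannot dominate later statistics. The wavelength grid is strictly
uniform (950–1650 nm in 5 nm steps → 141 bands for the reference
instrument); named wavelengths (1075, 1200 nm) resolve to the nearest
band center with ties broken toward the lower index — exact for
on-grid wavelengths, which is the only case the pipeline uses.

## Segmentation

Fruit/background contrast peaks near 1075 nm, so segmentation
thresholds the **raw DN** image at that band (published levels such as
737 and 942 are on the DN scale). The comparison is strictly greater
than the level; the convention is configurable because > vs ≥ is
genuinely ambiguous in common usage. Whether thresholding precedes or
follows flat-fielding is equally ambiguous; we threshold DN and apply
the mask to the reflectance cube, with reflectance-domain thresholding
available as an option. Cleanup is border-flood hole filling plus area
opening that drops components strictly smaller than `min_object_px`
(default 50 px). Components use 8-connectivity; a berry's "center" is
its pixel-rounded centroid. The calyx exclusion region is the closed
disc (squared distance ≤ r², default r = 5 px) around each center,
clipped to that berry's pixels.

## Spectral libraries and normalization

Library rows are single-pixel reflectance spectra in raster-scan
order. "Spectral normalization" is division of each spectrum by its
own band mean: it removes multiplicative illumination scaling exactly
(normalize(k·x) = normalize(x)), is idempotent, and preserves shape.
SNV (center + unit variance per spectrum) is provided as an
alternative; which normalization the original workflow used is not
recoverable, so both are implemented and the choice is recorded in
outputs. Balancing keeps the minority class whole and subsamples the
majority uniformly without replacement under a documented seed
(default 17).

## Classification

The classifier is a soft-margin RBF SVM at the library defaults of the
reference implementation: cost C = 1, kernel width γ = 1/#bands. No
hyperparameter search is performed — the baseline separability of the
two tissue classes is the point, and tuning is explicitly out of
scope. Cross-validation is stratified k-fold (k = 10); the quoted ±
spread is the standard deviation over `repeats` (default 5)
re-randomized fold assignments. Confusion statistics treat bruised as
the positive class and are reported as percentages rounded to two
decimals. Whole-image classification normalizes berry-pixel spectra
exactly as the training library was normalized; background and
calyx-excluded pixels never receive a tissue class.

## Bruise ratio index

Per berry: bruised pixels / (bruised + healthy pixels). Calyx-excluded
pixels are removed from the denominator as well as the numerator —
removing them only from the numerator would bias small berries toward
lower indices. Two-view indices average the stem- and calyx-side
ratios; berries are matched across views by the rank of their centers
in row-major order (the same physical tray is imaged from both sides,
so layout rank is preserved). A fruit is called bruised iff its index
strictly exceeds 0.2.

## Firmness and PLSR

Reference firmness is the least-squares slope (N/mm) of force vs
deformation restricted to 0.5–2.5 mm, where compression curves are
near-linear; samples outside the window never influence the fit.
PLSR relates per-berry mean reflectance spectra (calyx included — the
exclusion rule exists for classification, not whole-fruit spectra) to
firmness. Components are NIPALS latent directions; when not given, the
count is chosen by 10-fold cross-validation minimizing RMSEP, capped
at 20. At full rank PLSR reproduces ordinary least squares, which the
tests verify against a direct lstsq oracle. Mean spectra use raw
reflectance, not normalized spectra (configurable).

## Statistical battery

* **MANOVA** (one-way) on spectra: Wilks' Λ = det(W)/det(W+B) with
  Rao's F approximation, implemented directly and cross-checked
  against statsmodels. With p variables it requires n − g > p; with
  141 bands and few pixels the function refuses and suggests
  band-subsampling rather than silently regularizing.
* **Kruskal–Wallis** H with tie correction (chi-square p, df = g − 1).
* **Post hoc**: Dunn-type two-sided z-tests on mean joint ranks with
  tie-corrected variance, Bonferroni-adjusted over all pairs. The
  compact letter display is assembled by insertion over the
  non-significance graph, smallest group mean first, then absorbed
  subsets are dropped — a documented convention, since several valid
  letter assignments exist.
* **Regression**: OLS of index on human assessment; R² = 1 −
  SS_res/SS_tot, RMSE = √(SS_res/n).
* **Count ANOVA**: one-way F between two calling methods' per-replicate
  bruised counts; all-identical counts yield F = 0, p = 1 by
  convention (logged).

All tests are two-sided at α = 0.05. Null simulations in the test
suite verify empirical type-I error of KW and MANOVA within
[0.03, 0.07] over 500 replicates.

## Phantom generator

The generator emulates the acquisition the method targets: trays of
25 near-spherical berries (discs of radius 18–22 px; spheres project
to discs) on a dark background, placed on a jittered grid so
non-overlap is guaranteed, mirroring physical sample holders. Tissue
spectra are smooth baselines minus Gaussian absorption dips at
980/1200/1470 nm; the bruised variant is darker, has deeper dips, and
is clamped flat past 1470 nm while the healthy variant recovers —
healthy reflectance dominates bruised at every band. A dark calyx spot
(radius 4 px, flat 0.08 reflectance) sits at each berry center. True
bruise fractions are drawn per treatment (control 0; padded-surface
and steel-surface drop analogues 0.08–0.70; fully-bruised 0.92–1.0)
and realized exactly as pixel sets: by default a chord-bounded cap
growing from the stem (left) side, the side impacts hit hardest, or
optionally a disc-shaped blob that can miss the equatorial row
entirely. Scenes are converted to DN through a smooth multiplicative
illumination field (±15%), a gain mapping the white panel (0.99
reflectance) near full scale, additive Gaussian DN noise (sd 5), and
12-bit clipping; white/dark reference cubes share the same illumination
field so flat-fielding is exactly invertible in expectation. All
randomness flows from one seed through `SeedSequence` spawning (one
child stream each for geometry, fractions, spectra, sensor, firmness),
so scenes are bit-reproducible.

**Noise calibration.** Per-pixel tissue variation has two parts: a
multiplicative brightness jitter (sd 5%, removed by normalization) and
additive per-band reflectance noise. The additive sd default (0.12)
was calibrated once so that 10-fold CV accuracy of the default SVM on
ROI-extracted default-noise libraries lands in the mid-90s — the
regime the method operates in — and then frozen. Notably, at that
noise level CV errors are dominated not by spectral overlap but by
label contamination: the fully-bruised treatment leaves ~4% of
countable pixels healthy, and those enter the "bruised" ROI, exactly
as fully-bruised trays contaminate real spectral libraries.

**Reference measurements.** True firmness is linear in bruise
fraction, f = 2.9 − 1.6·fraction + ε (ε sd 0.08 N/mm, ≈5% of the
range), spanning realistic 1.3–2.9 N/mm readings. Force/deformation
curves sample 0–3 mm at 0.01 mm (301 points) with optional contact-toe
and plateau nonlinearities strictly outside the 0.5–2.5 mm fitting
window. Simulated human grading is the bruised/total ratio along the
berry's central (equatorial) row over calyx-excluded pixels, plus
truncated Gaussian noise (sd 0.08), clipped to [0, 1] — deliberately
blind to off-slice bruises, reproducing the failure mode of slice-based
inspection.

**What the phantom does not model**, and hence what passing tests do
not show about real fruit: specular glare and BRDF effects, partial-
volume mixing at berry edges, cultivar-specific spectral shape
differences (the two "datasets" differ only by a global illumination
scale, encoding the finding that normalization removes
between-experiment differences), bruise development over storage time,
and touching fruit (no watershed splitting is implemented because
holders keep berries apart). Real-fruit accuracies and R² values are
therefore not claims of this package; the simulation targets are.

## Problem sizes in the shipped checks

The acceptance script and tests use 12-berry trays for library
building (800 spectra per class), 20-berry trays across five
treatments (100 berries) for quantification and grader-agreement
measurements, n = 300 berries for PLSR coefficient recovery, and 500
null replicates per test-calibration estimate. These sizes were chosen
as the smallest that leave the measured quantities' sampling noise
well inside their acceptance bands.

## Known limitations

* The ENVI reader supports the common dialect (ASCII header,
  uncompressed BIL/BSQ/BIP, byte order 0, uint8/16, int16,
  float32/64); vendor-proprietary raw formats are out of scope.
* Berry matching across stem/calyx views assumes the tray layout is
  preserved between acquisitions; the exact physical protocol for
  correspondence is not recoverable, and the rank-matching rule is
  recorded in output metadata.
* MANOVA on all 141 bands needs thousands of pixels per group; the
  refusal-plus-subsample-flag behavior is deliberate.
* `simulate_human_assessment` grades a 2-D projection's central row,
  an analogue (not a model) of slicing a 3-D fruit.
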