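"""Firmness: slope from force/deformation curves, and PLSR prediction.

First measures firmness the reference way — the least-squares slope of
a parallel-plate compression curve over the 0.5-2.5 mm window — then
trains a PLSR model predicting firmness from mean berry spectra and
reports held-out RMSEP.  RMSEP well below sd(y) means the spectra carry
real firmness information.
"""

import numpy as np

import berrybruise as bb

# --- reference measurement: two representative berries ----------------
for true_slope in (1.46, 2.62):
    curve = bb.make_force_curve(true_slope, noise_sd=0.01, seed=0, nonlinear_ends=True)
    est = bb.firmness_slope(curve)
    print(f"true slope {true_slope:.2f} N/mm -> measured {est:.3f} N/mm")

# --- spectral prediction ----------------------------------------------
grid = bb.make_wavelength_grid(950, 1650, 5)
h, b = bb.healthy_spectrum(grid), bb.bruised_spectrum(grid)
rng = np.random.default_rng(3)
n = 300
fraction = rng.uniform(0, 1, n)
mean_spectra = (1 - fraction)[:, None] * h + fraction[:, None] * b
mean_spectra += rng.normal(0, 0.004, mean_spectra.shape)
firmness = 2.9 - 1.6 * fraction + rng.normal(0, 0.08, n)

train, test = slice(0, 240), slice(240, None)
model = bb.plsr_fit(mean_spectra[train], firmness[train])
pred = bb.plsr_predict(model, mean_spectra[test])
err = bb.rmsep(pred, firmness[test])
print(
    f"\nPLSR: {model.n_components} components, held-out RMSEP {err:.3f} N/mm "
    f"(response sd {np.std(firmness[test]):.3f} N/mm)"
)
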