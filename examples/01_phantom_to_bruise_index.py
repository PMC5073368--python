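"""From a hyperspectral scene to per-berry bruise ratio indices.

Generates a phantom tray of berries with known bruise fractions, runs
flat-field calibration, segmentation with calyx exclusion, pixel-level
SVM classification, and prints the estimated bruise ratio index next to
the generator's ground truth.  Estimates within ~0.01 of truth show the
whole chain working.
"""

import numpy as np

import berrybruise as bb

cfg = bb.PhantomConfig(rows=230, cols=230, n_berries=12)


def segment(scene):
    mask = bb.refine_mask(bb.threshold_mask(scene.raw.band(1075), 942), 50)
    labelmap = bb.label_components(mask)
    return labelmap, bb.calyx_exclusion_mask(labelmap, 5)


# 1. train the tissue classifier on ROI spectra from dedicated
#    control (healthy) and fully-bruised scenes
libs = []
for label, treatment, seed in (("healthy", "control", 1), ("bruised", "fully_bruised", 2)):
    scene = bb.make_scene(cfg, treatment, seed=seed)
    refl = bb.flat_field_correct(scene.raw, scene.white, scene.dark)
    labelmap, exclusion = segment(scene)
    lib = bb.extract_roi_spectra(refl, (labelmap.labels > 0) & ~exclusion, label)
    rng = np.random.default_rng(17)
    libs.append(lib.subset(np.sort(rng.choice(len(lib), 600, replace=False))))
lib = bb.normalize_library(bb.balance_library(bb.merge_libraries(*libs), 17))
cv_mean, cv_sd = bb.cross_validate(lib, k=10, repeats=2, seed=0)
print(f"10-fold CV accuracy of the tissue SVM: {cv_mean:.2f} +/- {cv_sd:.2f} %")
model = bb.train_classifier(lib)

# 2. classify a moderately bruised tray and quantify each berry
scene = bb.make_scene(cfg, "steel60", seed=11)
refl = bb.flat_field_correct(scene.raw, scene.white, scene.dark)
labelmap, exclusion = segment(scene)
classified = bb.classify_image(model, refl, labelmap, exclusion)

print(f"\nberries found: {labelmap.n_berries}")
print("berry   index   truth   bruised?")
for bid in labelmap.berry_ids():
    r, c = labelmap.centers[bid]
    tid = min(
        scene.truth.centers,
        key=lambda t: (scene.truth.centers[t][0] - r) ** 2
        + (scene.truth.centers[t][1] - c) ** 2,
    )
    ratio = bb.bruise_ratio(classified, bid)
    print(
        f"{bid:>5}   {ratio:.3f}   {scene.truth.fractions[tid]:.3f}   "
        f"{'yes' if bb.call_bruised(ratio) else 'no'}"
    )
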