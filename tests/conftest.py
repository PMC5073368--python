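"""Shared fixtures: small phantom scenes and an ROI-trained classifier.

Scenes are deliberately small (4 berries, 120x120 px) so the whole
suite runs in minutes on one CPU; the full 25-berry geometry is only
exercised where a test is about scene layout itself.
"""

import numpy as np
import pytest

import berrybruise as bb


def match_to_truth(labelmap, truth):
    """Detected berry id -> truth berry id, by nearest component center."""
    out = {}
    for bid, (r, c) in labelmap.centers.items():
        out[bid] = min(
            truth.centers,
            key=lambda t: (truth.centers[t][0] - r) ** 2 + (truth.centers[t][1] - c) ** 2,
        )
    return out


def segment_scene(scene, threshold_dn=942, min_object=50, calyx_radius=5):
    mask = bb.refine_mask(
        bb.threshold_mask(scene.raw.band(1075), threshold_dn), min_object
    )
    labelmap = bb.label_components(mask)
    exclusion = bb.calyx_exclusion_mask(labelmap, calyx_radius)
    return labelmap, exclusion


@pytest.fixture(scope="session")
def grid():
    return bb.make_wavelength_grid(950, 1650, 5)


@pytest.fixture(scope="session")
def pcfg_small():
    return bb.PhantomConfig(rows=120, cols=120, n_berries=4)


@pytest.fixture(scope="session")
def scene_lownoise():
    """Nearly noise-free scene: thresholding recovers the mask exactly."""
    cfg = bb.PhantomConfig(rows=120, cols=120, n_berries=4, spectral_noise_sd=0.01)
    return bb.make_scene(cfg, "steel60", seed=21)


@pytest.fixture(scope="session")
def scene_steel60(pcfg_small):
    return bb.make_scene(pcfg_small, "steel60", seed=3)


@pytest.fixture(scope="session")
def refl_steel60(scene_steel60):
    s = scene_steel60
    return bb.flat_field_correct(s.raw, s.white, s.dark)


@pytest.fixture(scope="session")
def trained_model(pcfg_small):
    """SVM trained on ROI-extracted libraries from control/fully-bruised scenes."""
    libs = []
    for label, treatment, s in (("healthy", "control", 1), ("bruised", "fully_bruised", 2)):
        scene = bb.make_scene(pcfg_small, treatment, seed=500 + s)
        refl = bb.flat_field_correct(scene.raw, scene.white, scene.dark)
        labelmap, exclusion = segment_scene(scene)
        roi = (labelmap.labels > 0) & ~exclusion
        lib = bb.extract_roi_spectra(refl, roi, label, treatment)
        rng = np.random.default_rng(17)
        keep = np.sort(rng.choice(len(lib), 400, replace=False))
        libs.append(lib.subset(keep))
    lib = bb.normalize_library(bb.balance_library(bb.merge_libraries(*libs), 17))
    return bb.train_classifier(lib)
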