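"""SVM training, cross-validation, evaluation and image classification."""

import numpy as np
import pytest

import berrybruise as bb
from berrybruise.classify import (
    BACKGROUND,
    BRUISED_CODE,
    EXCLUDED_CODE,
    HEALTHY_CODE,
    ConfusionMatrix,
)
from berrybruise.library import BRUISED, HEALTHY, SpectralLibrary
from conftest import match_to_truth, segment_scene


def separable_lib(n=60, sigma=0.05, seed=0, n_bands=5):
    """Two unit-separated Gaussian point clouds."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sigma, (n, n_bands)) + 1.0
    b = rng.normal(0.0, sigma, (n, n_bands)) + 2.0
    lib = SpectralLibrary(
        np.vstack([a, b]),
        np.array([HEALTHY] * n + [BRUISED] * n, dtype=object),
        950 + 5 * np.arange(n_bands),
        normalized=True,
    )
    return lib


class TestTrain:
    def test_separable_clouds_fit_perfectly(self):
        lib = separable_lib()
        model = bb.train_classifier(lib)
        pred = model.predict(lib.spectra)
        assert np.mean(pred == lib.class_labels.astype(str)) == 1.0

    def test_identically_distributed_classes_are_chance_level(self):
        rng = np.random.default_rng(1)
        lib = SpectralLibrary(
            rng.normal(size=(160, 4)),  # same distribution, labels carry no signal
            np.array([HEALTHY] * 80 + [BRUISED] * 80, dtype=object),
            950 + 5 * np.arange(4),
            normalized=True,
        )
        mean, _ = bb.cross_validate(lib, k=5, repeats=1, seed=0)
        assert 35 <= mean <= 65

    def test_single_class_rejected(self):
        lib = separable_lib()
        one = lib.subset(np.flatnonzero(lib.class_labels.astype(str) == HEALTHY))
        with pytest.raises(ValueError):
            bb.train_classifier(one)

    def test_unnormalized_library_rejected(self):
        lib = separable_lib()
        lib.normalized = False
        with pytest.raises(ValueError):
            bb.train_classifier(lib)

    def test_model_round_trip(self, tmp_path):
        model = bb.train_classifier(separable_lib())
        model.save(tmp_path / "model.joblib")
        back = bb.ClassifierModel.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(
            back.predict(np.full((1, 5), 1.0)), model.predict(np.full((1, 5), 1.0))
        )


class TestCrossValidate:
    def test_separable_library_is_perfect(self):
        mean, sd = bb.cross_validate(separable_lib(), k=5, repeats=2, seed=0)
        assert mean == 100.0 and sd == 0.0

    def test_label_shuffled_is_chance(self):
        lib = separable_lib(n=60)
        rng = np.random.default_rng(2)
        shuffled = lib.class_labels.copy()
        rng.shuffle(shuffled)
        lib.class_labels = shuffled
        mean, _ = bb.cross_validate(lib, k=5, repeats=1, seed=0)
        assert 30 <= mean <= 70

    def test_deterministic_under_seed(self):
        lib = separable_lib(sigma=0.6)
        a = bb.cross_validate(lib, k=5, repeats=2, seed=3)
        b = bb.cross_validate(lib, k=5, repeats=2, seed=3)
        assert a == b

    def test_k_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError):
            bb.cross_validate(separable_lib(n=5), k=10)


class TestEvaluate:
    def test_train_equals_test_on_separable_data(self):
        lib = separable_lib()
        cm = bb.evaluate(bb.train_classifier(lib), lib)
        assert cm.fn == 0 and cm.fp == 0
        assert cm.tp + cm.tn == len(lib)

    def test_empty_test_library_rejected(self):
        model = bb.train_classifier(separable_lib())
        empty = SpectralLibrary(
            np.empty((0, 5)), np.array([], dtype=object),
            950 + 5 * np.arange(5), normalized=True,
        )
        with pytest.raises(ValueError):
            bb.evaluate(model, empty)

    def test_grid_mismatch_rejected(self):
        model = bb.train_classifier(separable_lib(n_bands=5))
        other = separable_lib(n_bands=4)
        with pytest.raises(ValueError):
            bb.evaluate(model, other)

    def test_cross_dataset_accuracy_close_to_cv(self):
        # two "datasets" share tissue spectra; illumination differences are
        # removed by normalization, so train-on-A/test-on-B tracks A's CV
        cfg_a = bb.PhantomConfig(rows=120, cols=120, n_berries=4)
        cfg_b = bb.PhantomConfig(
            rows=120, cols=120, n_berries=4, illumination_scale=1.25
        )
        from berrybruise.phantom import make_library

        lib_a = bb.normalize_library(make_library(cfg_a, 250, seed=1, source_tag="A"))
        lib_b = bb.normalize_library(make_library(cfg_b, 250, seed=2, source_tag="B"))
        cv_mean, _ = bb.cross_validate(lib_a, k=5, repeats=1, seed=0)
        cm = bb.evaluate(bb.train_classifier(lib_a), lib_b)
        acc_b = bb.confusion_stats(cm)["accuracy_pct"]
        assert abs(cv_mean - acc_b) <= 3.0


class TestConfusionStats:
    def test_published_combined_confusion_percentages(self):
        stats = bb.confusion_stats(ConfusionMatrix(tp=42773, fn=2193, fp=1179, tn=43787))
        assert stats["tpr_pct"] == 95.12
        assert stats["tnr_pct"] == 97.38
        assert stats["fpr_pct"] == 2.62
        assert stats["accuracy_pct"] == 96.25
        assert round(stats["tnr_pct"] - stats["tpr_pct"], 2) == 2.26

    def test_perfect_and_zero_cases(self):
        perfect = bb.confusion_stats(ConfusionMatrix(1, 0, 0, 1))
        assert perfect["accuracy_pct"] == 100.0 and perfect["tpr_pct"] == 100.0
        worst = bb.confusion_stats(ConfusionMatrix(0, 1, 1, 0))
        assert worst["accuracy_pct"] == 0.0

    def test_rate_complements(self):
        stats = bb.confusion_stats(ConfusionMatrix(30, 12, 7, 51))
        assert stats["fpr_pct"] == round(100 - stats["tnr_pct"], 2)
        assert stats["fnr_pct"] == round(100 - stats["tpr_pct"], 2)
        assert all(0 <= v <= 100 for v in stats.values())

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            bb.confusion_stats(ConfusionMatrix(0, 0, 3, 4))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)


class TestClassifyImage:
    def test_background_and_excluded_never_tissue(
        self, trained_model, refl_steel60, scene_steel60
    ):
        labelmap, exclusion = segment_scene(scene_steel60)
        ci = bb.classify_image(trained_model, refl_steel60, labelmap, exclusion)
        assert np.all(ci.classes[labelmap.labels == 0] == BACKGROUND)
        assert np.all(ci.classes[exclusion & (labelmap.labels > 0)] == EXCLUDED_CODE)
        tissue = np.isin(ci.classes, [HEALTHY_CODE, BRUISED_CODE])
        assert not (tissue & (labelmap.labels == 0)).any()

    def test_pixelwise_agreement_with_truth(
        self, trained_model, refl_steel60, scene_steel60
    ):
        labelmap, exclusion = segment_scene(scene_steel60)
        ci = bb.classify_image(trained_model, refl_steel60, labelmap, exclusion)
        countable = (labelmap.labels > 0) & ~exclusion
        pred_bruised = ci.classes == BRUISED_CODE
        agreement = np.mean(
            (pred_bruised == scene_steel60.truth.bruise_mask)[countable]
        )
        assert agreement >= 0.95

    def test_healthy_berries_have_few_bruised_pixels(self, trained_model, pcfg_small):
        scene = bb.make_scene(pcfg_small, "control", seed=9)
        refl = bb.flat_field_correct(scene.raw, scene.white, scene.dark)
        labelmap, exclusion = segment_scene(scene)
        ci = bb.classify_image(trained_model, refl, labelmap, exclusion)
        for bid in labelmap.berry_ids():
            mask = labelmap.berry_mask(bid)
            frac = np.mean(ci.classes[mask] == BRUISED_CODE)
            assert frac <= 0.01

    def test_full_exclusion_excludes_everything(self, trained_model, refl_steel60, scene_steel60):
        labelmap, _ = segment_scene(scene_steel60)
        everything = labelmap.labels > 0
        ci = bb.classify_image(trained_model, refl_steel60, labelmap, everything)
        assert not np.isin(ci.classes, [HEALTHY_CODE, BRUISED_CODE]).any()

    def test_shape_mismatch_rejected(self, trained_model, refl_steel60, scene_steel60):
        labelmap, _ = segment_scene(scene_steel60)
        with pytest.raises(ValueError):
            bb.classify_image(
                trained_model, refl_steel60, labelmap, np.zeros((3, 3), bool)
            )
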