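"""Synthetic phantom generator: spectra, scenes, curves, assessments."""

import dataclasses

import numpy as np
import pytest

import berrybruise as bb
from berrybruise.cube import band_index
from berrybruise.phantom import make_library


class TestTissueSpectra:
    def test_healthy_recovers_after_global_minimum(self, grid):
        h = bb.healthy_spectrum(grid)
        assert h[band_index(grid, 1650)] > h[band_index(grid, 1470)]

    def test_bruised_stays_flat_after_minimum(self, grid):
        b = bb.bruised_spectrum(grid)
        assert abs(b[band_index(grid, 1650)] - b[band_index(grid, 1470)]) < 0.02

    def test_healthy_dominates_bruised_everywhere(self, grid):
        assert np.all(bb.healthy_spectrum(grid) >= bb.bruised_spectrum(grid))

    def test_water_absorption_dips_are_local_minima(self, grid):
        h = bb.healthy_spectrum(grid)
        for nm in (980, 1200, 1470):
            i = band_index(grid, nm)
            window = h[max(i - 8, 0) : i + 9]
            assert h[i] == window.min()
        assert np.argmin(h) == band_index(grid, 1470)  # global minimum

    def test_calyx_darker_than_tissue(self, grid):
        assert np.all(bb.calyx_spectrum(grid) < bb.bruised_spectrum(grid))


class TestMakeScene:
    def test_control_has_zero_fractions(self, pcfg_small):
        scene = bb.make_scene(pcfg_small, "control", seed=1)
        assert all(f == 0.0 for f in scene.truth.fractions.values())
        assert not scene.truth.bruise_mask.any()

    def test_fully_bruised_fractions_high(self, pcfg_small):
        scene = bb.make_scene(pcfg_small, "fully_bruised", seed=1)
        assert all(f >= 0.9 for f in scene.truth.fractions.values())

    def test_same_seed_bit_identical(self, pcfg_small):
        a = bb.make_scene(pcfg_small, "steel60", seed=5)
        b = bb.make_scene(pcfg_small, "steel60", seed=5)
        np.testing.assert_array_equal(a.raw.data, b.raw.data)
        np.testing.assert_array_equal(a.white.data, b.white.data)
        np.testing.assert_array_equal(a.dark.data, b.dark.data)

    def test_different_seed_differs(self, pcfg_small):
        a = bb.make_scene(pcfg_small, "steel60", seed=5)
        b = bb.make_scene(pcfg_small, "steel60", seed=6)
        assert not np.array_equal(a.raw.data, b.raw.data)

    def test_dn_range_and_reference_ordering(self, scene_steel60):
        for cube in (scene_steel60.raw, scene_steel60.white, scene_steel60.dark):
            assert cube.data.min() >= 0 and cube.data.max() <= 4095
        # white >= raw nearly everywhere (noise can flip isolated cells)
        assert np.mean(scene_steel60.white.data >= scene_steel60.raw.data) > 0.99
        assert scene_steel60.dark.data.mean() < scene_steel60.raw.data.mean()

    def test_numeric_fraction_hits_target(self, pcfg_small):
        scene = bb.make_scene(pcfg_small, 0.3, seed=2)
        for bid, f in scene.truth.fractions.items():
            assert f == pytest.approx(0.3, abs=0.01)

    def test_bruise_mask_inside_berries_outside_calyx_disc(self, scene_steel60):
        truth = scene_steel60.truth
        assert not (truth.bruise_mask & (truth.labels == 0)).any()
        for bid in truth.centers:
            countable = truth.countable_mask(bid)
            in_berry = truth.bruise_mask & (truth.labels == bid)
            assert not (in_berry & ~countable).any()

    def test_truth_fraction_consistent_with_masks(self, scene_steel60):
        truth = scene_steel60.truth
        for bid, frac in truth.fractions.items():
            countable = truth.countable_mask(bid)
            measured = (truth.bruise_mask & countable).sum() / countable.sum()
            assert measured == pytest.approx(frac, abs=1e-9)

    def test_unknown_treatment_rejected(self, pcfg_small):
        with pytest.raises(KeyError):
            bb.make_scene(pcfg_small, "nonexistent", seed=1)

    def test_scene_too_small_rejected(self):
        cfg = bb.PhantomConfig(rows=50, cols=50, n_berries=25)
        with pytest.raises(ValueError):
            bb.make_scene(cfg, "control", seed=1)


class TestForceCurve:
    def test_noise_free_recovers_slope_exactly(self):
        curve = bb.make_force_curve(2.0, noise_sd=0.0)
        assert bb.firmness_slope(curve) == pytest.approx(2.0)

    def test_standard_sampling_has_301_points(self):
        assert len(bb.make_force_curve(1.0, noise_sd=0.0).deformation) == 301

    def test_representative_firm_sample_recovery(self):
        # 2.62 N/mm: a firm berry reading
        slopes = [
            bb.firmness_slope(bb.make_force_curve(2.62, noise_sd=0.01, seed=s))
            for s in range(5)
        ]
        assert all(abs(s - 2.62) <= 0.02 for s in slopes)

    def test_nonlinear_ends_do_not_bias_window_slope(self):
        curve = bb.make_force_curve(1.8, noise_sd=0.0, nonlinear_ends=True)
        assert bb.firmness_slope(curve) == pytest.approx(1.8, abs=1e-9)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            bb.make_force_curve(0.0)


class TestHumanAssessment:
    def test_fully_bruised_graded_near_one(self, pcfg_small):
        # every countable pixel bruised -> slice grade exactly 1
        scene = bb.make_scene(pcfg_small, 1.0, seed=3)
        graded = bb.simulate_human_assessment(scene.truth, noise_sd=0.0, seed=0)
        assert all(v == 1.0 for v in graded.values())
        # the fully-bruised treatment (>= 92% area) still grades high
        scene = bb.make_scene(pcfg_small, "fully_bruised", seed=3)
        graded = bb.simulate_human_assessment(scene.truth, noise_sd=0.0, seed=0)
        assert all(v >= 0.75 for v in graded.values())

    def test_control_graded_near_zero(self, pcfg_small):
        scene = bb.make_scene(pcfg_small, "control", seed=3)
        graded = bb.simulate_human_assessment(scene.truth, noise_sd=0.0, seed=0)
        assert all(v == 0.0 for v in graded.values())

    def test_off_slice_blob_is_invisible_to_grader(self):
        # a shallow bruise away from the equatorial row: the image index
        # sees it, the slice-based grader does not
        cfg = bb.PhantomConfig(
            rows=120, cols=120, n_berries=4, bruise_shape="blob"
        )
        found = False
        for seed in range(20):
            scene = bb.make_scene(cfg, 0.15, seed=seed)
            graded = bb.simulate_human_assessment(scene.truth, noise_sd=0.0, seed=0)
            for bid, f in scene.truth.fractions.items():
                if f > 0.1 and graded[bid] <= 0.02:
                    found = True
        assert found

    def test_values_bounded(self, scene_steel60):
        graded = bb.simulate_human_assessment(scene_steel60.truth, noise_sd=0.3, seed=1)
        assert all(0.0 <= v <= 1.0 for v in graded.values())

    def test_deterministic_under_seed(self, scene_steel60):
        a = bb.simulate_human_assessment(scene_steel60.truth, seed=4)
        b = bb.simulate_human_assessment(scene_steel60.truth, seed=4)
        assert a == b


class TestMakeLibrary:
    def test_shapes_and_labels(self, pcfg_small):
        lib = make_library(pcfg_small, 50, seed=1)
        assert len(lib) == 100
        assert lib.class_counts() == {"healthy": 50, "bruised": 50}
        assert lib.n_bands == 141

    def test_cv_accuracy_monotone_in_noise(self, pcfg_small):
        # accuracy should not improve as spectral noise grows
        means = []
        for sd in (0.12, 0.4, 0.6):
            accs = []
            for seed in range(5):
                cfg = dataclasses.replace(pcfg_small, spectral_noise_sd=sd)
                lib = bb.normalize_library(make_library(cfg, 150, seed=seed))
                accs.append(bb.cross_validate(lib, k=5, repeats=1, seed=0)[0])
            means.append(np.mean(accs))
        assert means[0] >= means[1] >= means[2]
        assert means[0] - means[2] > 1.0  # and noise genuinely degrades it
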