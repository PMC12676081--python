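"""Decay fitting, FastFLIM, component maps and lifetime segmentation."""

import numpy as np
import pytest

from paleoflim import flim as fl
from paleoflim import scenes as sc
from .conftest import pooled_histogram


def noiseless_histogram(params, acq, irf, photons=1e5):
    return sc.expected_class_decay(params, acq, irf) * photons


class TestFastFLIM:
    def test_zero_pixel_is_undefined(self, irf, acq_fast):
        cube = fl.FLIMCube(np.zeros((256, 2, 2)), acq_fast.bin_width_ns,
                           acq_fast.period_ns)
        tau = fl.fast_flim(cube, irf)
        assert np.all(np.isnan(tau))

    def test_single_exponential_mean_matches_lifetime(self, irf, acq):
        params = sc.DecayClassParams((1.0,), (1.0,))
        h = noiseless_histogram(params, acq, irf)
        cube = fl.FLIMCube(h[:, None, None], acq.bin_width_ns, acq.period_ns)
        tau = fl.fast_flim(cube, irf, min_photons=1)[0, 0]
        assert abs(tau - 1.0) < acq.bin_width_ns

    def test_amplitude_mixture_gives_intensity_weighted_mean(self, irf, acq):
        # 50/50 amplitudes of 0.3 and 6.0 ns: (0.5*0.3^2 + 0.5*6^2)/(0.5*0.3 + 0.5*6)
        params = sc.DecayClassParams((0.5, 0.5), (0.3, 6.0))
        expected = (0.5 * 0.3**2 + 0.5 * 6.0**2) / (0.5 * 0.3 + 0.5 * 6.0)
        h = noiseless_histogram(params, acq, irf)
        cube = fl.FLIMCube(h[:, None, None], acq.bin_width_ns, acq.period_ns)
        tau = fl.fast_flim(cube, irf, min_photons=1)[0, 0]
        assert abs(tau - expected) < acq.bin_width_ns

    def test_min_photons_must_be_positive(self, irf, acq_fast):
        cube = fl.FLIMCube(np.zeros((256, 1, 1)), acq_fast.bin_width_ns,
                           acq_fast.period_ns)
        with pytest.raises(ValueError):
            fl.fast_flim(cube, irf, min_photons=0)


class TestFitDecay:
    def test_single_exponential_recovered_exactly(self, irf, acq):
        h = noiseless_histogram(sc.DecayClassParams((1.0,), (1.7,)), acq, irf)
        fit = fl.fit_decay(h, acq.bin_width_ns, irf, k=1)
        assert fit.converged
        assert abs(fit.lifetimes_ns[0] - 1.7) / 1.7 < 1e-4

    def test_triple_exponential_recovered_on_noiseless_data(self, irf, acq):
        params = sc.default_decay_params()["fungal"]
        h = noiseless_histogram(params, acq, irf)
        fit = fl.fit_decay(h, acq.bin_width_ns, irf, k=3)
        np.testing.assert_allclose(fit.lifetimes_ns, params.lifetimes_ns, rtol=0.01)
        np.testing.assert_allclose(fit.amplitude_fractions, params.amplitudes,
                                   atol=0.02)

    def test_noiseless_fit_reproduces_histogram(self, irf, acq):
        # oracle equivalence: refit model matches the input to 1e-6 of peak
        params = sc.default_decay_params()["plant_other"]
        h = noiseless_histogram(params, acq, irf)
        fit = fl.fit_decay(h, acq.bin_width_ns, irf, k=3)
        model = fit.model(acq.n_bins, acq.bin_width_ns, irf)
        assert np.max(np.abs(model - h)) < 1e-6 * h.max()

    def test_pooled_fungal_region_recovers_picosecond_component(self, default_scene_run, irf):
        _, label, cube, _, _, _ = default_scene_run
        pooled = pooled_histogram(cube, label, "fungal")
        fit = fl.fit_decay(pooled, cube.bin_width_ns, irf, k=3)
        assert abs(fit.lifetimes_ns[0] - 0.3) / 0.3 < 0.05

    def test_insufficient_photons_rejected(self, irf, acq_fast):
        h = np.zeros(acq_fast.n_bins)
        h[40] = 20  # 20 photons < 10*3
        with pytest.raises(ValueError, match="photons"):
            fl.fit_decay(h, acq_fast.bin_width_ns, irf, k=3)

    def test_sorting_invariant_under_initial_permutation(self, irf, acq):
        params = sc.default_decay_params()["fungal"]
        h = noiseless_histogram(params, acq, irf)
        fits = [fl.fit_decay(h, acq.bin_width_ns, irf, k=3, init_lifetimes_ns=init)
                for init in ([0.3, 2.0, 6.5], [6.5, 0.3, 2.0], [2.0, 6.5, 0.3])]
        for fit in fits:
            assert np.all(np.diff(fit.lifetimes_ns) > 0)
            np.testing.assert_allclose(fit.lifetimes_ns, fits[0].lifetimes_ns,
                                       rtol=1e-3)

    def test_fastflim_and_fit_agree_for_single_exponential(self, irf, acq):
        h = noiseless_histogram(sc.DecayClassParams((1.0,), (2.5,)), acq, irf)
        cube = fl.FLIMCube(h[:, None, None], acq.bin_width_ns, acq.period_ns)
        tau_fast = fl.fast_flim(cube, irf, min_photons=1)[0, 0]
        fit = fl.fit_decay(h, acq.bin_width_ns, irf, k=1)
        assert abs(tau_fast - fit.lifetimes_ns[0]) < acq.bin_width_ns

    def test_parameter_recovery_under_poisson_noise(self, irf, acq):
        # median relative lifetime error < 5% for every component over 100
        # seeded replicates of the default-scene pooled decay at 1e5 photons
        spec = sc.default_scene(seed=0)
        label = sc.generate_structure_masks(spec)
        params = sc.default_decay_params()
        taus = np.asarray(params["fungal"].lifetimes_ns)
        pooled = np.zeros(acq.n_bins)
        for name, class_id in sc.CLASS_IDS.items():
            n_px = int((label == class_id).sum())
            budget = (spec.background_photons_per_pixel if name == "background"
                      else spec.photons_per_pixel)
            pooled += n_px * budget * sc.expected_class_decay(params[name], acq, irf)
        expected = pooled / pooled.sum() * 1e5
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(100):
            fit = fl.fit_decay(rng.poisson(expected), acq.bin_width_ns, irf, k=3,
                               init_lifetimes_ns=taus)
            errors.append(np.abs(fit.lifetimes_ns - taus) / taus)
        med = np.median(np.array(errors), axis=0)
        assert np.all(med < 0.05)


class TestFitCube:
    def test_cube_of_zeros_gives_undefined_maps(self, irf, acq_fast):
        cube = fl.FLIMCube(np.zeros((256, 4, 4)), acq_fast.bin_width_ns,
                           acq_fast.period_ns)
        table, maps = fl.fit_cube(cube, irf, k=2)
        assert len(table) == 0
        assert np.all(maps.undefined)
        assert np.all(np.isnan(maps.component_intensity))

    def test_uniform_single_class_image_converges_to_class_parameters(self, irf, acq):
        mask = np.full((6, 6), sc.CLASS_IDS["fungal"], dtype=np.uint8)
        cube, _ = sc.generate_flim_cube(mask, irf=irf, acquisition=acq,
                                        photons_per_pixel=2000, seed=3)
        table, maps = fl.fit_cube(cube, irf, k=3)
        params = sc.default_decay_params()["fungal"]
        np.testing.assert_allclose(maps.lifetimes_ns, params.lifetimes_ns, rtol=0.05)
        # per-pixel amplitude scatter stays centred on the truth
        frac1 = maps.component_intensity[0] / np.nansum(maps.component_intensity, axis=0)
        truth_frac1 = params.amplitudes[0] * params.lifetimes_ns[0] / np.sum(
            np.array(params.amplitudes) * np.array(params.lifetimes_ns))
        assert abs(np.nanmedian(frac1) - truth_frac1) < 0.05

    def test_component_maps_show_tissue_contrast(self, default_scene_run):
        _, label, _, truth, _, maps = default_scene_run
        short_map, long_map = maps.component_intensity[0], maps.component_intensity[2]
        fungal = truth.class_mask("fungal")
        plant = truth.class_mask("plant_other")
        # short component bright in fungal tissue, dim in plant tissue
        assert np.nanmedian(short_map[fungal]) > 10 * np.nanmedian(short_map[plant])
        # long component present in both organic tissues (fungus plus plant),
        # but within plant tissue it dominates over the short component
        assert np.nanmedian(long_map[fungal]) > 0
        assert np.nanmedian(long_map[plant]) > 10 * np.nanmedian(short_map[plant])

    def test_spatial_binning_must_be_supported(self, irf, acq_fast):
        cube = fl.FLIMCube(np.zeros((256, 4, 4)), acq_fast.bin_width_ns,
                           acq_fast.period_ns)
        with pytest.raises(ValueError):
            fl.fit_cube(cube, irf, spatial_binning=3)


class TestLifetimeMask:
    def test_all_background_scene_gives_empty_mask(self, irf, acq_fast):
        mask = np.zeros((12, 12), dtype=np.uint8)
        cube, _ = sc.generate_flim_cube(mask, irf=irf, acquisition=acq_fast,
                                        background_photons_per_pixel=200, seed=2)
        _, maps = fl.fit_cube(cube, irf, k=3)
        out = fl.lifetime_mask(maps)
        assert not out.mask.any()

    def test_mask_selects_short_lifetime_tissue_only(self, default_scene_run):
        _, _, _, truth, _, maps = default_scene_run
        out = fl.lifetime_mask(maps)
        plant = truth.class_mask("plant_other")
        assert (out.mask & plant).sum() < 0.01 * plant.sum()
        fungal_vesicle = truth.class_mask("fungal", "plant_vesicle")
        inter = (out.mask & fungal_vesicle).sum()
        union = (out.mask | fungal_vesicle).sum()
        assert inter / union >= 0.9

    def test_fraction_cut_validated(self, default_scene_run):
        *_, maps = default_scene_run
        with pytest.raises(ValueError):
            fl.lifetime_mask(maps, fraction_cut=1.5)


class TestMaxProjection:
    def test_single_slice_identity(self):
        a = np.random.default_rng(0).random((5, 5))
        np.testing.assert_array_equal(fl.max_projection([a]), a)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        stack = [rng.random((8, 8)) for _ in range(3)]
        out = fl.max_projection(stack)
        brute = np.maximum(np.maximum(stack[0], stack[1]), stack[2])
        np.testing.assert_array_equal(out, brute)

    def test_dominating_slice_is_returned(self):
        rng = np.random.default_rng(2)
        base = [rng.random((4, 4)) for _ in range(2)]
        top = np.maximum(base[0], base[1]) + 1.0
        np.testing.assert_array_equal(fl.max_projection(base + [top]), top)

    def test_nan_pixels_ignored_unless_everywhere(self):
        a = np.array([[1.0, np.nan]])
        b = np.array([[np.nan, np.nan]])
        out = fl.max_projection([a, b])
        assert out[0, 0] == 1.0
        assert np.isnan(out[0, 1])

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            fl.max_projection([])
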