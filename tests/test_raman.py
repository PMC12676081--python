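"""Calibration, baseline correction, band fitting, dispersion and La."""

import numpy as np
import pytest

from paleoflim import raman as rm
from paleoflim import scenes as sc


def make_fit(positions_heights, success=True):
    peaks = {name: rm.PeakModel(center_cm1=c, fwhm_cm1=60.0, height=h)
             for name, (c, h) in positions_heights.items()}
    return rm.BandFitResult(peaks=peaks, residual_rms=0.0, success=success)


class TestPhotonEnergy:
    @pytest.mark.parametrize("wl,ev", [(1239.842, 1.0), (514.0, 2.4122), (633.0, 1.9587)])
    def test_known_conversions(self, wl, ev):
        assert rm.to_photon_energy(wl) == pytest.approx(ev, abs=1e-4)

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValueError):
            rm.to_photon_energy(0.0)


class TestCalibration:
    @staticmethod
    def si_spectrum(offset=0.0):
        return sc.generate_raman_spectrum(sc.silicon_reference_material(), 514.0,
                                          noise="none", axis_offset_cm1=offset)

    def test_measured_at_reference_is_identity(self):
        spec = self.si_spectrum()
        out = rm.calibrate(
            rm.RamanSpectrum(spec.wavenumber_cm1, spec.intensity, 514.0,
                             calibrated=False),
            520.7)
        np.testing.assert_allclose(out.wavenumber_cm1, spec.wavenumber_cm1)

    def test_offset_axis_restored_to_reference_position(self):
        spec = self.si_spectrum(offset=1.3)
        measured = rm.measure_line_position(spec, (500.0, 545.0))
        assert measured == pytest.approx(522.0, abs=0.05)
        out = rm.calibrate(spec, measured)
        assert rm.measure_line_position(out, (500.0, 545.0)) == pytest.approx(
            520.7, abs=0.05)

    def test_rigid_shift_moves_every_band_equally(self):
        # G generated at 1609.3 with Si read at 522.0 lands on 1608.0
        mat = sc.RamanMaterial(
            name="t", baseline_poly=(10.0,),
            bands=(sc.Band("Si", 520.7, 0.0, 6.0, 500.0),
                   sc.Band("G", 1608.0, 0.0, 56.0, 300.0)))
        spec = sc.generate_raman_spectrum(mat, 514.0, noise="none",
                                          axis_offset_cm1=1.3)
        assert rm.measure_line_position(spec, (1560.0, 1660.0)) == pytest.approx(
            1609.3, abs=0.05)
        out = rm.calibrate(spec, rm.measure_line_position(spec, (500.0, 545.0)))
        assert rm.measure_line_position(out, (1560.0, 1660.0)) == pytest.approx(
            1608.0, abs=0.05)
        # pairwise band distances unchanged by the shift
        gap_before = (rm.measure_line_position(spec, (1560.0, 1660.0))
                      - rm.measure_line_position(spec, (500.0, 545.0)))
        gap_after = (rm.measure_line_position(out, (1560.0, 1660.0))
                     - rm.measure_line_position(out, (500.0, 545.0)))
        assert gap_after == pytest.approx(gap_before, abs=1e-9)

    def test_idempotent_once_calibrated(self):
        spec = self.si_spectrum(offset=1.3)
        once = rm.calibrate(spec, 522.0)
        twice = rm.calibrate(once, 555.0)  # second measurement ignored
        np.testing.assert_array_equal(once.wavenumber_cm1, twice.wavenumber_cm1)

    def test_out_of_window_si_position_rejected(self):
        spec = self.si_spectrum(offset=1.3)  # uncalibrated axis
        with pytest.raises(ValueError, match="wrong line"):
            rm.calibrate(spec, 470.0)


class TestBaseline:
    def test_reference_equal_to_bandless_spectrum_gives_zero(self):
        spec = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
        out = rm.baseline_correct(spec, reference=spec)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-8)

    def test_noiseless_band_heights_recovered_within_two_percent(self):
        mat = sc.arbuscule_material()
        spec = sc.generate_raman_spectrum(mat, 514.0, noise="none")
        ref = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
        corrected = rm.baseline_correct(spec, reference=ref)
        fit = rm.fit_bands(corrected)
        truth = {b.name: b.height for b in mat.bands}
        for name in rm.MAIN_BANDS:
            assert fit.peaks[name].height == pytest.approx(truth[name], rel=0.02)

    def test_reference_axis_mismatch_rejected(self):
        spec = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
        short_axis = spec.wavenumber_cm1[:-10]
        ref = rm.RamanSpectrum(short_axis, spec.intensity[:-10], 514.0)
        with pytest.raises(ValueError, match="axis"):
            rm.baseline_correct(spec, reference=ref)


class TestFitBands:
    def test_single_pure_lorentzian_recovered_to_high_precision(self):
        axis = np.arange(1000.0, 2000.0, 1.0)
        g = 56.0 / 2.0
        y = 100.0 * g**2 / ((axis - 1608.0) ** 2 + g**2)
        spec = rm.RamanSpectrum(axis, y, 514.0, calibrated=True)
        fit = rm.fit_bands(spec, band_windows={"G": (1560.0, 1660.0)})
        assert fit.peaks["G"].center_cm1 == pytest.approx(1608.0, rel=1e-3)
        assert fit.peaks["G"].fwhm_cm1 == pytest.approx(56.0, rel=1e-3)
        assert fit.peaks["G"].height == pytest.approx(100.0, rel=1e-3)

    def test_noiseless_default_fixture_returns_anchor_positions(self, noiseless_carbon_fit):
        fit = noiseless_carbon_fit
        assert fit.success
        assert fit.peaks["D"].center_cm1 == pytest.approx(1358.0, abs=0.5)
        assert fit.peaks["G"].center_cm1 == pytest.approx(1608.0, abs=0.5)
        for name, (lo, hi) in fit.windows.items():
            assert lo <= fit.peaks[name].center_cm1 <= hi

    def test_fwhm_recovery_under_poisson_noise(self):
        errors = []
        for i in range(15):
            spec = sc.generate_raman_spectrum(sc.arbuscule_material(), 514.0,
                                              seed=100 + i, noise="poisson")
            ref = sc.generate_raman_spectrum(sc.background_material(), 514.0,
                                             seed=900 + i, noise="poisson")
            fit = rm.fit_bands(rm.baseline_correct(spec, reference=ref))
            errors.append(abs(fit.peaks["G"].fwhm_cm1 - 56.0))
        assert np.median(errors) < 2.0

    def test_flat_spectrum_flags_failure(self):
        axis = np.arange(1000.0, 2000.0, 1.0)
        spec = rm.RamanSpectrum(axis, np.full_like(axis, 7.0), 514.0, calibrated=True)
        fit = rm.fit_bands(spec, band_windows={"G": (1560.0, 1660.0)})
        assert not fit.success
        assert fit.peaks == {}

    def test_uncalibrated_spectrum_rejected(self):
        axis = np.arange(1000.0, 2000.0, 1.0)
        spec = rm.RamanSpectrum(axis, np.zeros_like(axis), 514.0, calibrated=False)
        with pytest.raises(ValueError, match="calibrated"):
            rm.fit_bands(spec)


class TestDispersion:
    def test_identical_positions_give_zero_slope(self):
        fits = [(make_fit({"G": (1600.0, 1.0), "D": (1350.0, 1.0)}), wl)
                for wl in (457.0, 514.0, 633.0)]
        assert rm.dispersion(fits, "G").slope_cm1_per_ev == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form_slope(self):
        wl_a = 1239.842 / 2.0   # 2.0 eV
        wl_b = 1239.842 / 3.0   # 3.0 eV
        fits = [(make_fit({"G": (1600.0, 1.0)}), wl_a),
                (make_fit({"G": (1610.0, 1.0)}), wl_b)]
        assert rm.dispersion(fits, "G").slope_cm1_per_ev == pytest.approx(10.0)

    def test_six_wavelength_recovery_of_generator_dispersions(self):
        mat = sc.arbuscule_material()
        ref_mat = sc.background_material()
        fits = []
        for wl in (325.0, 457.0, 488.0, 514.0, 532.0, 633.0):
            spec = sc.generate_raman_spectrum(mat, wl, noise="none")
            ref = sc.generate_raman_spectrum(ref_mat, wl, noise="none")
            fits.append((rm.fit_bands(rm.baseline_correct(spec, reference=ref)), wl))
        assert rm.dispersion(fits, "G").slope_cm1_per_ev == pytest.approx(8.3, abs=0.2)
        assert rm.dispersion(fits, "D").slope_cm1_per_ev == pytest.approx(4.1, abs=0.2)

    def test_single_point_rejected(self):
        fits = [(make_fit({"G": (1600.0, 1.0)}), 514.0)]
        with pytest.raises(ValueError, match=">= 2"):
            rm.dispersion(fits, "G")


class TestIntensityRatioAndLa:
    def test_equal_heights_give_unity(self):
        fit = make_fit({"D": (1358.0, 50.0), "G": (1608.0, 50.0)})
        assert rm.intensity_ratio(fit) == pytest.approx(1.0)

    def test_height_ratio_arithmetic(self):
        fit = make_fit({"D": (1358.0, 60.0), "G": (1608.0, 100.0)})
        assert rm.intensity_ratio(fit) == pytest.approx(0.6)

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rm.intensity_ratio(make_fit({"G": (1608.0, 100.0)}))

    def test_nanocrystalline_closed_form(self):
        est = rm.estimate_la(0.55, photon_energy_ev=2.41, regime="nanocrystalline_FR")
        assert est.la_nm == pytest.approx(1.0, rel=1e-6)

    def test_la_monotone_in_ratio(self):
        ratios = np.linspace(0.05, 1.5, 30)
        fr = [rm.estimate_la(r, regime="nanocrystalline_FR").la_nm for r in ratios]
        tk = [rm.estimate_la(r, regime="graphitic_TK").la_nm for r in ratios]
        assert np.all(np.diff(fr) > 0)
        assert np.all(np.diff(tk) < 0)

    def test_la_vanishes_with_the_ratio_in_fr_regime(self):
        las = [rm.estimate_la(r, regime="nanocrystalline_FR").la_nm
               for r in (1e-4, 1e-3, 1e-2)]
        assert np.all(np.diff(las) > 0) and las[0] < 0.02

    def test_auto_regime_uses_g_width(self):
        broad = rm.estimate_la(0.5, regime="auto", fwhm_g_cm1=56.0)
        narrow = rm.estimate_la(0.5, regime="auto", fwhm_g_cm1=20.0)
        assert broad.regime == "nanocrystalline_FR"
        assert narrow.regime == "graphitic_TK"

    def test_auto_without_g_width_rejected(self):
        with pytest.raises(ValueError, match="fwhm_g"):
            rm.estimate_la(0.5, regime="auto")


class TestBandMapAndSummary:
    def test_all_baseline_grid_maps_to_zero(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        grid = sc.generate_raman_map(mask, step_um=10.0, pixel_size_um=1.0, noise="none")
        ref = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
        bmap = rm.map_band(grid, band="G", reference=ref)
        assert np.all(bmap.intensity == 0.0)

    def test_g_intensity_confined_to_annulus_grid_points(self):
        spec = sc.SceneSpec(width_px=60, height_px=60, pixel_size_um=1.0, structures=(
            sc.Structure("annulus", "fungal",
                         {"cx": 30.0, "cy": 30.0, "inner_radius": 14.0,
                          "thickness": 8.0}),))
        mask = sc.generate_structure_masks(spec)
        grid = sc.generate_raman_map(mask, step_um=6.0, pixel_size_um=1.0, noise="none")
        ref = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
        bmap = rm.map_band(grid, band="G", reference=ref)
        inside = grid.labels == sc.CLASS_IDS["fungal"]
        assert np.all(bmap.intensity[inside] > 500)
        assert np.all(bmap.intensity[~inside] < 1.0)

    def test_noiseless_summary_matches_generator_truth(self, noiseless_carbon_fit):
        summary = rm.summarize_carbon({514.0: noiseless_carbon_fit})
        assert summary.pos_d_cm1 == pytest.approx(1358.0, abs=0.5)
        assert summary.pos_g_cm1 == pytest.approx(1608.0, abs=0.5)
        assert summary.fwhm_g_cm1 == pytest.approx(56.0, abs=1.0)
        assert summary.idig == pytest.approx(0.55, abs=0.01)
        assert summary.regime == "nanocrystalline_FR"

    def test_single_wavelength_summary_flags_missing_dispersion(self, noiseless_carbon_fit):
        summary = rm.summarize_carbon({514.0: noiseless_carbon_fit})
        assert summary.disp_d_cm1_per_ev is None
        assert summary.disp_g_cm1_per_ev is None
        assert any("single excitation" in f for f in summary.flags)

    def test_arbuscule_and_vesicle_summaries_match_for_identical_material(self):
        # two structures carrying the same carbon material summarize identically
        mat = sc.arbuscule_material()
        ref = sc.generate_raman_spectrum(sc.background_material(), 514.0, noise="none")
        summaries = []
        for _ in range(2):
            spec = sc.generate_raman_spectrum(mat, 514.0, noise="none")
            fit = rm.fit_bands(rm.baseline_correct(spec, reference=ref))
            summaries.append(rm.summarize_carbon({514.0: fit}))
        assert summaries[0].idig == pytest.approx(summaries[1].idig, rel=1e-6)
        assert summaries[0].la_nm == pytest.approx(summaries[1].la_nm, rel=1e-6)

    def test_missing_anchor_wavelength_rejected(self, noiseless_carbon_fit):
        with pytest.raises(ValueError, match="514"):
            rm.summarize_carbon({633.0: noiseless_carbon_fit})
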