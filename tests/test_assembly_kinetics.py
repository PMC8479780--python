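"""Two-step mechanism: simulation, limits, fitting and spectral diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photokin import synthetic_data as syn
from photokin.assembly_kinetics import (
    TwoStepModel,
    difference_spectrum,
    fit_two_step,
    qband_peak_track,
    simulate_two_step,
    spectra_from_profiles,
)
from photokin.bands import GaussianBand
from photokin.global_fitting import GlobalExpModel, global_exp_fit
from photokin.spectral_io import Spectrum, bin_wavelength

from conftest import make_matrix


class TestSimulateTwoStep:
    def test_no_flux_when_uptake_is_off(self):
        p = simulate_two_step(TwoStepModel(0.0, 0.5, 4.6, 2.4),
                              np.linspace(0, 100, 20))
        assert np.allclose(p.free_bilin, 2.4)
        assert np.allclose(p.covalent, 0.0)

    def test_irreversible_first_step_saturates_noncovalent(self):
        p = simulate_two_step(TwoStepModel(1e6, 0.0, 4.6, 2.4),
                              np.linspace(0, 50, 30))
        assert p.free_bilin[-1] == pytest.approx(0.0, abs=1e-6)
        assert p.noncovalent[-1] == pytest.approx(2.4, rel=1e-6)
        assert np.all(p.covalent == 0.0)

    def test_fast_uptake_limit_matches_first_order_closed_form(self):
        # k1*A0/k2 ~ 5e4: attachment-limited, covalent rise is single-exp
        model = TwoStepModel(k1=1e8, k2=0.01, A0=4.6, B0=2.4)
        t = np.linspace(0.02, 600, 400)
        p = simulate_two_step(model, t)
        mask = t > 5.0 / (model.k1 * 1e-6 * model.A0)
        ref = model.B0 * (1.0 - np.exp(-model.k2 * t[mask]))
        assert np.max(np.abs(p.covalent[mask] - ref) / model.B0) < 1e-3

    @given(
        k1=st.floats(1e2, 1e6), k2=st.floats(1e-3, 1.0),
        a0=st.floats(1.0, 10.0), b0=st.floats(0.5, 5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_mass_conservation_both_ledgers(self, k1, k2, a0, b0):
        model = TwoStepModel(k1, k2, a0, b0)
        p = simulate_two_step(model, np.geomspace(0.1, 2000, 25))
        bilin = p.free_bilin + p.noncovalent + p.covalent
        protein = p.apo + p.noncovalent + p.covalent
        assert np.max(np.abs(bilin - b0)) / b0 < 1e-8
        assert np.max(np.abs(protein - a0)) / a0 < 1e-8

    def test_monotone_species_trajectories(self):
        p = simulate_two_step(TwoStepModel(5e4, 0.05, 4.6, 2.4),
                              np.linspace(0, 400, 100))
        assert np.all(np.diff(p.covalent) >= -1e-10)
        assert np.all(np.diff(p.free_bilin) <= 1e-10)

    def test_pseudo_first_order_uptake_rate(self):
        # A0 >> B0: the non-covalent rise rate approaches k1*A0
        model = TwoStepModel(k1=1e4, k2=0.0, A0=500.0, B0=1.0)
        t = np.linspace(0.0, 2000.0, 300)
        p = simulate_two_step(model, t)
        k_eff = model.k1 * 1e-6 * model.A0
        ref = model.B0 * (1.0 - np.exp(-k_eff * t))
        assert np.max(np.abs(p.noncovalent - ref)) < 0.02 * model.B0


class TestSpectraFromProfiles:
    def grid(self):
        return np.linspace(550, 750, 41)

    def species(self):
        return {
            name: sp.spectrum(self.grid())
            for name, sp in syn._pcb_species().items()
        }

    def test_zero_concentrations_give_zero_matrix(self):
        p = simulate_two_step(TwoStepModel(0.0, 0.0, 1.0, 1e-12),
                              np.linspace(0, 10, 6))
        p.free_bilin[:] = 0.0
        m = spectra_from_profiles(p, self.species())
        assert np.allclose(m.values, 0.0)

    def test_single_species_matrix_has_rank_one(self):
        p = simulate_two_step(TwoStepModel(0.0, 0.0, 1.0, 2.4),
                              np.linspace(0, 10, 6))
        p.free_bilin = np.linspace(2.4, 0.4, 6)
        m = spectra_from_profiles(p, self.species())
        s = np.linalg.svd(m.values, compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_missing_species_rejected(self):
        p = simulate_two_step(TwoStepModel(0.0, 0.0, 1.0, 1.0), [0.0, 1.0])
        species = self.species()
        species.pop("covalent")
        with pytest.raises(ValueError, match="covalent"):
            spectra_from_profiles(p, species)

    def test_default_pcb_final_spectrum_peaks_at_649(self):
        scenario = syn.default_pcb_assembly(seed=0)
        scenario.noise_sigma = 0.0
        m = syn.simulate_assembly(scenario)
        peak = m.wavelengths[np.argmax(m.values[-1])]
        assert peak == pytest.approx(649.0, abs=1.0)


class TestFitTwoStep:
    def test_noiseless_self_recovery(self):
        scenario = syn.default_bv_assembly_two_step(seed=0)
        scenario.noise_sigma = 0.0
        scenario.time_grid = np.arange(1.0, 1501.0, 25.0)
        data = bin_wavelength(syn.simulate_assembly(scenario), 20)
        fit = fit_two_step(data, TwoStepModel(1e3, 0.05, 4.6, 2.40))
        assert fit.model.k1 == pytest.approx(scenario.model.k1, rel=0.01)
        assert fit.model.k2 == pytest.approx(scenario.model.k2, rel=0.01)

    def test_k1_only_lower_bound_when_uptake_beats_dead_time(self):
        scenario = syn.default_pcb_assembly(seed=0)
        scenario.noise_sigma = 0.0
        scenario.time_grid = np.arange(1.0, 151.0, 2.5)
        data = bin_wavelength(syn.simulate_assembly(scenario), 20)
        fit = fit_two_step(data, TwoStepModel(5e5, 0.03, 4.6, 2.40))
        assert fit.metadata.get("k1_lower_bound_only")
        # k2 stays identifiable even though k1 saturates
        assert fit.model.k2 == pytest.approx(1.0 / 18.0, rel=0.02)

    def test_attachment_limited_k2_matches_single_exp_fit(self):
        scenario = syn.default_pcb_assembly(seed=0)
        scenario.noise_sigma = 0.0
        scenario.time_grid = np.arange(1.0, 151.0, 2.5)
        data = bin_wavelength(syn.simulate_assembly(scenario), 20)
        ode_fit = fit_two_step(data, TwoStepModel(5e5, 0.03, 4.6, 2.40))
        exp_fit = global_exp_fit(data, GlobalExpModel(n_exp=1, with_offset=True))
        assert ode_fit.model.k2 == pytest.approx(1.0 / exp_fit.taus[0], rel=0.02)

    def test_exponential_fit_deviates_late_when_uptake_limits(self):
        """With rate-limiting second-order uptake the kinetics are not
        exponential: a 1-exp fit leaves structured late-time residuals that
        the mechanistic fit does not."""
        scenario = syn.default_bv_assembly_two_step(seed=0)
        scenario.noise_sigma = 0.0
        scenario.time_grid = np.arange(1.0, 1501.0, 25.0)
        data = bin_wavelength(syn.simulate_assembly(scenario), 20)
        ode_fit = fit_two_step(data, TwoStepModel(1e3, 0.05, 4.6, 2.40))
        exp_fit = global_exp_fit(data, GlobalExpModel(n_exp=1, with_offset=True))
        late = data.times > 800.0
        late_exp = np.sqrt(np.mean(
            (data.values[late] - exp_fit.model_eval.values[late]) ** 2))
        late_ode = np.sqrt(np.mean(
            (data.values[late] - ode_fit.model_eval.values[late]) ** 2))
        assert late_exp > 10.0 * late_ode


class TestDifferenceSpectrum:
    def test_equal_times_give_zero(self):
        m = make_matrix([1.0, 2.0, 3.0], [500.0, 510.0],
                        np.arange(6.0).reshape(3, 2))
        d = difference_spectrum(m, 2.0, 2.0)
        assert np.all(d.values == 0.0)

    def test_linear_in_time_matrix_scales_with_dt(self, rng):
        profile = rng.normal(size=5)
        times = np.linspace(0, 10, 11)
        m = make_matrix(times, np.arange(5.0) + 500,
                        times[:, None] * profile[None, :])
        d1 = difference_spectrum(m, 4.0, 2.0)
        d2 = difference_spectrum(m, 8.0, 2.0)
        assert d2.values == pytest.approx(3.0 * d1.values)

    def test_default_bv_late_minus_early_signature(self):
        """Late-minus-early difference: negative lobe where the 705+ nm
        intermediate decayed, positive lobe at the 697 nm covalent band."""
        scenario = syn.default_bv_assembly(seed=3)
        m = bin_wavelength(syn.simulate_assembly_biexp(scenario), 7)
        d = difference_spectrum(m, 120.0, m.times[0])
        red = (m.wavelengths > 712) & (m.wavelengths < 740)
        core = (m.wavelengths > 688) & (m.wavelengths < 702)
        assert d.values[red].min() < 0
        assert d.values[core].max() > 0

    def test_time_outside_range_rejected(self):
        m = make_matrix([1.0, 2.0], [500.0, 510.0], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="outside"):
            difference_spectrum(m, 5.0, 1.0)


class TestPeakTracking:
    def test_static_gaussian_peak_is_band_center(self, rng):
        grid = np.linspace(600, 800, 81)
        band = GaussianBand(697.3, 40.0, 0.2)
        values = np.tile(band(grid), (5, 1)) + rng.normal(0, 1e-5, (5, 81))
        m = make_matrix(np.arange(5.0) + 1, grid, values)
        peaks = qband_peak_track(m, (650.0, 760.0))
        assert np.max(np.abs(peaks - 697.3)) < 0.1

    def test_crossover_switches_bands_against_argmax_oracle(self):
        grid = np.linspace(600, 800, 201)
        b1 = GaussianBand(660.0, 30.0, 1.0)
        b2 = GaussianBand(730.0, 30.0, 1.0)
        # 22 points so no slice hits the exact 50/50 amplitude tie
        weights = np.linspace(0, 1, 22)
        values = np.outer(1 - weights, b1(grid)) + np.outer(weights, b2(grid))
        m = make_matrix(np.arange(22.0) + 1, grid, values)
        peaks = qband_peak_track(m, (610.0, 790.0))
        dense = np.linspace(610, 790, 20001)
        for i, w in enumerate(weights):
            oracle = dense[np.argmax((1 - w) * b1(dense) + w * b2(dense))]
            assert abs(peaks[i] - oracle) < 0.5

    def test_flat_slice_reports_missing(self):
        m = make_matrix([1.0, 2.0], np.linspace(600, 700, 11),
                        np.vstack([np.zeros(11), np.ones(11) * 2]))
        peaks = qband_peak_track(m, (600.0, 700.0))
        assert np.isnan(peaks).all()
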