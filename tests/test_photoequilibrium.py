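"""Photostationary decomposition and pump-probe subtraction tests."""

import numpy as np
import pytest

from photokin import synthetic_data as syn
from photokin.bands import GaussianBand, SpeciesSpectrum
from photokin.photoequilibrium import (
    determine_subtraction_factor,
    scale_factor_for_pump,
    subtract_ta_datasets,
)
from photokin.spectral_io import Spectrum

from conftest import make_matrix


def dense_scan_oracle(equil, dark, marker, noise_floor, step=0.005,
                      negativity_mult=3.0, smooth_window=9):
    """Independent descending scan over s with the negativity criterion."""
    s0 = equil.at(marker) / dark.at(marker)
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    for s in np.arange(s0, -step, -step):
        s = max(s, 0.0)
        phot = equil.values - s * dark.values
        sm = np.convolve(np.pad(phot, pad, mode="edge"), kernel,
                         mode="same")[pad:pad + phot.size]
        if sm.min() >= -negativity_mult * noise_floor:
            return s
    return 0.0


class TestSubtractionFactor:
    def test_pure_dark_state_gives_unity(self):
        scenario = syn.default_pcb_equilibrium(seed=0)
        scenario.dark_fraction = 1.0
        scenario.noise_sigma = 0.0
        dark, equil = syn.simulate_equilibrium(scenario)
        res = determine_subtraction_factor(equil, dark, 649.0, 1e-4)
        assert res.s == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(res.S_phot.values)) < 1e-9

    def test_noiseless_mixture_recovers_dark_fraction_exactly(self):
        """With the photoproduct transparent at the marker, s equals the
        generating dark fraction to grid resolution."""
        for factory, marker, f in (
            (syn.default_pcb_equilibrium, 649.0, 0.22),
            (syn.default_bv_equilibrium, 697.0, 0.35),
        ):
            scenario = factory(seed=0)
            scenario.noise_sigma = 0.0
            dark, equil = syn.simulate_equilibrium(scenario)
            res = determine_subtraction_factor(equil, dark, marker, 1e-4)
            assert res.s == pytest.approx(f, abs=0.005)
            phot = scenario.photoproduct_spectrum.evaluate(
                scenario.wavelength_grid
            )
            assert res.S_phot.values == pytest.approx(
                (1 - f) * phot, abs=2e-3
            )

    def test_noise_robustness_over_twenty_replicates(self):
        errors = []
        for seed in range(20):
            scenario = syn.default_bv_equilibrium(seed=seed)
            dark, equil = syn.simulate_equilibrium(scenario)
            res = determine_subtraction_factor(
                equil, dark, 697.0, scenario.noise_sigma
            )
            errors.append(abs(res.s - scenario.dark_fraction))
        assert max(errors) <= 0.02

    def test_monotone_in_dark_fraction(self):
        estimates = []
        for f in (0.1, 0.3, 0.5, 0.7):
            scenario = syn.default_pcb_equilibrium(seed=1)
            scenario.dark_fraction = f
            dark, equil = syn.simulate_equilibrium(scenario)
            res = determine_subtraction_factor(equil, dark, 649.0, 1e-3)
            estimates.append(res.s)
        assert np.all(np.diff(estimates) > 0)

    def test_absorbing_photoproduct_binds_negativity_constraint(self):
        """A photoproduct with real absorbance at the marker inflates s0;
        the negativity criterion must pull s back down, flagged, and agree
        with an independent dense scan."""
        scenario = syn.default_pcb_equilibrium(seed=0)
        scenario.noise_sigma = 0.0
        scenario.photoproduct_spectrum = SpeciesSpectrum("photoproduct", [
            GaussianBand(545.0, 55.0, 0.16),
            GaussianBand(649.0, 45.0, 0.03),  # deliberate marker absorbance
        ])
        dark, equil = syn.simulate_equilibrium(scenario)
        noise_floor = 1e-3
        res = determine_subtraction_factor(equil, dark, 649.0, noise_floor)
        assert res.constrained
        assert res.s < res.s0
        oracle = dense_scan_oracle(equil, dark, 649.0, noise_floor)
        assert res.s == pytest.approx(oracle, abs=0.005)

    def test_inconsistent_mixture_rejected(self):
        grid = np.linspace(500, 700, 201)
        dark = Spectrum(grid, GaussianBand(649, 60, 0.1)(grid))
        equil = Spectrum(grid, 1.5 * dark.values)
        with pytest.raises(ValueError, match="exceeds 1"):
            determine_subtraction_factor(equil, dark, 649.0, 1e-4)

    def test_dark_state_without_marker_band_rejected(self):
        grid = np.linspace(500, 700, 201)
        dark = Spectrum(grid, GaussianBand(540, 40, 0.1)(grid))
        equil = Spectrum(grid, 0.5 * dark.values)
        with pytest.raises(ValueError, match="too small"):
            determine_subtraction_factor(equil, dark, 690.0, 1e-3)

    def test_resamples_dark_spectrum_onto_equil_grid(self):
        scenario = syn.default_pcb_equilibrium(seed=0)
        scenario.noise_sigma = 0.0
        dark, equil = syn.simulate_equilibrium(scenario)
        coarse = Spectrum(dark.wavelengths[::2], dark.values[::2])
        res = determine_subtraction_factor(equil, coarse, 649.0, 1e-3)
        assert res.s == pytest.approx(0.22, abs=0.01)


class TestPumpScaling:
    def test_equal_spectra_leave_factor_unchanged(self):
        grid = np.linspace(350, 750, 100)
        sp = Spectrum(grid, GaussianBand(385, 60, 0.3)(grid) + 0.05)
        assert scale_factor_for_pump(0.22, sp, sp, 385.0) == pytest.approx(0.22)

    def test_ratio_arithmetic(self):
        grid = np.linspace(350, 450, 11)
        dark = Spectrum(grid, np.full(11, 0.11))
        equil = Spectrum(grid, np.full(11, 0.10))
        s_ta = scale_factor_for_pump(0.22, dark, equil, 385.0)
        assert s_ta == pytest.approx(0.242, rel=1e-12)

    def test_zero_factor_stays_zero(self):
        grid = np.linspace(350, 450, 11)
        sp = Spectrum(grid, np.ones(11))
        assert scale_factor_for_pump(0.0, sp, sp, 385.0) == 0.0

    def test_nonpositive_reference_rejected(self):
        grid = np.linspace(350, 450, 11)
        dark = Spectrum(grid, np.ones(11))
        equil = Spectrum(grid, np.zeros(11))
        with pytest.raises(ValueError, match="non-positive"):
            scale_factor_for_pump(0.5, dark, equil, 385.0)


class TestTASubtraction:
    def grids(self):
        return np.geomspace(10, 20000, 12), np.linspace(500, 700, 21)

    def test_zero_factor_is_identity(self, rng):
        t, wl = self.grids()
        a = make_matrix(t, wl, rng.normal(size=(12, 21)),
                        time_unit="ps", value_unit="mOD")
        b = make_matrix(t, wl, rng.normal(size=(12, 21)),
                        time_unit="ps", value_unit="mOD")
        out = subtract_ta_datasets(a, b, 0.0)
        assert np.array_equal(out.values, a.values)

    def test_constructed_mixture_recovers_pure_component(self, rng):
        t, wl = self.grids()
        pure = rng.normal(size=(12, 21))
        dark = rng.normal(size=(12, 21))
        s_ta = 0.242
        mixed = make_matrix(t, wl, pure + s_ta * dark,
                            time_unit="ps", value_unit="mOD")
        dark_m = make_matrix(t, wl, dark, time_unit="ps", value_unit="mOD")
        out = subtract_ta_datasets(mixed, dark_m, s_ta)
        assert out.values == pytest.approx(pure, abs=1e-12)

    def test_mismatched_grids_rejected(self, rng):
        t, wl = self.grids()
        a = make_matrix(t, wl, rng.normal(size=(12, 21)),
                        time_unit="ps", value_unit="mOD")
        b = make_matrix(t, wl + 1.0, rng.normal(size=(12, 21)),
                        time_unit="ps", value_unit="mOD")
        with pytest.raises(ValueError, match="re-bin"):
            subtract_ta_datasets(a, b, 0.1)
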