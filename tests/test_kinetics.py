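"""Rate equations, their closed-form limits and independent-integrator oracles."""

import math

import numpy as np
import pytest

from photokin.constants import AVOGADRO
from photokin.kinetics import (
    ExperimentGeometry,
    KineticState,
    PhotoswitchSystem,
    QuantumYields,
    absorbed_fraction,
    effective_irradiation_times,
    photostationary_state,
    rate_monochromatic,
    rate_polychromatic,
    simulate,
    species_photon_share,
)
from photokin.kinetics import _rate_factor
from photokin.photonflux import IrradiationSource
from photokin.spectra import Spectrum
from photokin.synthetic import make_led_profile


class TestAbsorbedFraction:
    @pytest.mark.parametrize("abs_tot,expected", [(0.0, 0.0), (1.0, 0.9), (2.0, 0.99)])
    def test_decadic_values(self, abs_tot, expected):
        assert absorbed_fraction(abs_tot) == pytest.approx(expected, abs=1e-15)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            absorbed_fraction(-0.1)


class TestPhotonShares:
    def test_single_absorber_takes_all(self):
        assert species_photon_share(0.8, 0.0) == (1.0, 0.0)

    def test_symmetric_split(self):
        assert species_photon_share(0.3, 0.3) == (0.5, 0.5)

    def test_direct_ratio(self):
        sA, sB = species_photon_share(0.8, 0.2)
        assert sA == pytest.approx(0.8)
        assert sB == pytest.approx(0.2)

    def test_no_absorber_rejected(self):
        with pytest.raises(ZeroDivisionError):
            species_photon_share(0.0, 0.0)

    def test_photon_bookkeeping(self):
        # q_A + q_B = q0 * absorbed fraction at any composition
        q0 = 1.7e15
        abs_A, abs_B = 0.37, 0.21
        sA, sB = species_photon_share(abs_A, abs_B)
        P = absorbed_fraction(abs_A + abs_B)
        assert q0 * sA * P + q0 * sB * P == pytest.approx(q0 * P, rel=1e-14)


class TestRateFactorLimit:
    def test_tends_to_ln10(self):
        assert _rate_factor(0.0) == pytest.approx(math.log(10.0), rel=1e-12)

    def test_continuous_at_series_switch(self):
        # relative jump across the analytic-switch threshold < 1e-10
        below = _rate_factor(1e-6 * (1 - 1e-9))
        above = _rate_factor(1e-6 * (1 + 1e-9))
        assert abs(below - above) / above < 1e-10


class TestMonochromaticRate:
    def test_dark_and_no_thermal_is_static(self, toy_system, geometry):
        dark = IrradiationSource(photon_flux=0.0, wavelength_nm=340.0)
        system = PhotoswitchSystem(toy_system.eps_A, toy_system.eps_B, k_BA=0.0)
        dA, dB = rate_monochromatic(
            KineticState(2e-5, 1e-5), system, QuantumYields(0.2, 0.4), dark, geometry
        )
        assert dA == 0.0 and dB == 0.0

    def test_thermal_only_rate_product(self, toy_system, geometry):
        # k_BA = 7.2e-7 s^-1 on 1e-5 M of B gives d[A]/dt = 7.2e-12 M/s
        dark = IrradiationSource(photon_flux=0.0, wavelength_nm=340.0)
        dA, dB = rate_monochromatic(
            KineticState(0.0, 1e-5),
            toy_system,
            QuantumYields(0.2, 0.4),
            dark,
            geometry,
        )
        assert dA == pytest.approx(7.2e-12, rel=1e-12)
        assert dB == -dA

    @pytest.mark.parametrize(
        "conc_A,conc_B", [(4e-5, 0.0), (2.5e-5, 1.5e-5), (1e-6, 3.9e-5), (0.0, 4e-5)]
    )
    def test_matches_stepwise_photon_accounting_oracle(
        self, conc_A, conc_B, toy_system, geometry, mono_340, true_phis
    ):
        # independent oracle: explicitly form q_A and q_B (photon shares times
        # absorbed fraction), then combine with the yields and thermal term
        lam = mono_340.wavelength_nm
        eA, eB = toy_system.eps_A(lam), toy_system.eps_B(lam)
        l = geometry.path_irradiation
        abs_A, abs_B = conc_A * eA * l, conc_B * eB * l
        if abs_A + abs_B == 0:
            pytest.skip("no absorber")
        P = absorbed_fraction(abs_A + abs_B)
        sA, sB = species_photon_share(abs_A, abs_B)
        qA = mono_340.photon_flux * sA * P
        qB = mono_340.photon_flux * sB * P
        oracle = (
            -true_phis.phi_AB * qA / (AVOGADRO * geometry.volume_L)
            + true_phis.phi_BA * qB / (AVOGADRO * geometry.volume_L)
            + toy_system.k_BA * conc_B
        )
        dA, dB = rate_monochromatic(
            KineticState(conc_A, conc_B), toy_system, true_phis, mono_340, geometry
        )
        assert dA == pytest.approx(oracle, rel=1e-14, abs=1e-30)
        assert dB == -dA


class TestPolychromaticRate:
    def test_narrow_spike_matches_monochromatic(
        self, toy_system, geometry, mono_340, true_phis
    ):
        spike = make_led_profile(340.0, 1e-3)
        poly = IrradiationSource(photon_flux=mono_340.photon_flux, emission=spike)
        state = KineticState(2.5e-5, 1.5e-5)
        dA_poly, dB_poly = rate_polychromatic(state, toy_system, true_phis, poly, geometry)
        dA_mono, _ = rate_monochromatic(state, toy_system, true_phis, mono_340, geometry)
        assert dA_poly == pytest.approx(dA_mono, rel=1e-6)
        assert dB_poly == -dA_poly

    def test_empty_cuvette_is_static(self, toy_system, geometry, true_phis):
        led = make_led_profile(340.0, 12.0)
        poly = IrradiationSource(photon_flux=1.7e15, emission=led)
        dA, dB = rate_polychromatic(
            KineticState(0.0, 0.0), toy_system, true_phis, poly, geometry
        )
        assert dA == 0.0 and dB == 0.0

    def test_grid_refinement_converges(self, toy_system, geometry, true_phis):
        state = KineticState(2.5e-5, 1.5e-5)
        rates = []
        for n in (161, 321):
            led = make_led_profile(340.0, 12.0, n_points=n)
            poly = IrradiationSource(photon_flux=1.7e15, emission=led)
            rates.append(
                rate_polychromatic(state, toy_system, true_phis, poly, geometry)[0]
            )
        assert abs(rates[1] - rates[0]) / abs(rates[1]) < 1e-4

    def test_no_spectral_overlap_rejected(self, geometry, true_phis):
        wl = np.linspace(300.0, 400.0, 101)
        eps = Spectrum(wl, np.full_like(wl, 100.0), kind="molar_absorptivity")
        system = PhotoswitchSystem(eps, eps, k_BA=0.0)
        led = make_led_profile(550.0, 5.0)
        poly = IrradiationSource(photon_flux=1e15, emission=led)
        with pytest.raises(ValueError, match="overlap"):
            rate_polychromatic(KineticState(1e-5, 0.0), system, true_phis, poly, geometry)


class TestSimulate:
    def test_dark_thermal_decay_is_exponential(self, toy_system, geometry, true_phis):
        dark = IrradiationSource(photon_flux=0.0, wavelength_nm=340.0)
        k = 5e-4  # faster thermal rate so the decay is visible in 2 h
        system = PhotoswitchSystem(toy_system.eps_A, toy_system.eps_B, k_BA=k)
        times = np.linspace(0.0, 7200.0, 25)
        b0 = 3e-5
        traj = simulate(
            system, true_phis, dark, geometry, KineticState(0.0, b0), times
        )
        np.testing.assert_allclose(traj.conc_B, b0 * np.exp(-k * times), rtol=1e-6)

    def test_total_concentration_conserved(self, noiseless_experiment):
        exp = noiseless_experiment
        total = exp.truth.conc_A + exp.truth.conc_B
        np.testing.assert_allclose(
            total, exp.initial_state.total, rtol=1e-10, atol=0.0
        )

    def test_matches_fixed_step_rk4_oracle(
        self, toy_system, geometry, mono_340, true_phis
    ):
        # independent integrator: classical RK4 at a small fixed step
        times = np.linspace(0.0, 600.0, 21)
        initial = KineticState(4e-5, 0.0)
        traj = simulate(toy_system, true_phis, mono_340, geometry, initial, times)

        c_tot = initial.total
        lam = mono_340.wavelength_nm
        eA, eB = toy_system.eps_A(lam), toy_system.eps_B(lam)

        def f(a):
            b = c_tot - a
            abs_A, abs_B = a * eA, b * eB
            x = abs_A + abs_B
            factor = math.log(10.0) if x < 1e-12 else (1 - 10**(-x)) / x
            return (
                mono_340.photon_flux
                / (AVOGADRO * geometry.volume_L)
                * factor
                * (true_phis.phi_BA * abs_B - true_phis.phi_AB * abs_A)
                + toy_system.k_BA * b
            )

        h = 0.05
        a = initial.conc_A
        rk4 = [a]
        t = 0.0
        for target in times[1:]:
            while t < target - h / 2:
                k1 = f(a)
                k2 = f(a + h / 2 * k1)
                k3 = f(a + h / 2 * k2)
                k4 = f(a + h * k3)
                a += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            rk4.append(a)
        np.testing.assert_allclose(traj.conc_A, rk4, rtol=1e-6)

    def test_invariant_under_output_time_refinement(
        self, toy_system, geometry, mono_340, true_phis
    ):
        initial = KineticState(4e-5, 0.0)
        coarse = np.linspace(0.0, 1200.0, 11)
        fine = np.linspace(0.0, 1200.0, 101)
        tc = simulate(toy_system, true_phis, mono_340, geometry, initial, coarse)
        tf = simulate(toy_system, true_phis, mono_340, geometry, initial, fine)
        np.testing.assert_allclose(tc.conc_A, tf.conc_A[::10], rtol=1e-8)

    def test_monotone_approach_to_stationary_state(self, noiseless_experiment):
        exp = noiseless_experiment
        frac_A_pss, _ = photostationary_state(
            exp.system, exp.true_phis, exp.source, exp.geometry,
            total_conc=exp.initial_state.total,
        )
        gap = np.abs(exp.truth.conc_A / exp.initial_state.total - frac_A_pss)
        assert np.all(np.diff(gap) <= 1e-12)


class TestPhotostationaryState:
    def _flat_system(self, eps_A_val, eps_B_val, k_BA=0.0):
        wl = np.linspace(300.0, 400.0, 11)
        return PhotoswitchSystem(
            Spectrum(wl, np.full_like(wl, eps_A_val), kind="molar_absorptivity"),
            Spectrum(wl, np.full_like(wl, eps_B_val), kind="molar_absorptivity"),
            k_BA=k_BA,
        )

    def test_symmetric_system_gives_half_half(self, geometry):
        system = self._flat_system(1000.0, 500.0)
        phis = QuantumYields(0.2, 0.4)  # phi_AB*eps_A == phi_BA*eps_B
        src = IrradiationSource(photon_flux=1e15, wavelength_nm=350.0)
        fa, fb = photostationary_state(system, phis, src, geometry)
        assert fa == pytest.approx(0.5, abs=1e-10)
        assert fb == pytest.approx(0.5, abs=1e-10)

    def test_closed_form_without_thermal_relaxation(
        self, toy_system, geometry, mono_340, true_phis
    ):
        system = PhotoswitchSystem(toy_system.eps_A, toy_system.eps_B, k_BA=0.0)
        fa, fb = photostationary_state(system, true_phis, mono_340, geometry)
        eA, eB = system.eps_A(340.0), system.eps_B(340.0)
        ratio = (true_phis.phi_AB * eA) / (true_phis.phi_BA * eB)  # [B]/[A]
        assert fb / fa == pytest.approx(ratio, rel=1e-10)

    def test_dark_equilibrium_is_all_stable_isomer(self, toy_system, geometry, true_phis):
        dark = IrradiationSource(photon_flux=0.0, wavelength_nm=340.0)
        fa, fb = photostationary_state(toy_system, true_phis, dark, geometry)
        assert (fa, fb) == (1.0, 0.0)

    def test_thermal_rate_shifts_pss_toward_stable_isomer(
        self, toy_system, geometry, mono_340, true_phis
    ):
        no_thermal = PhotoswitchSystem(toy_system.eps_A, toy_system.eps_B, k_BA=0.0)
        fast_thermal = PhotoswitchSystem(toy_system.eps_A, toy_system.eps_B, k_BA=1e-3)
        fa0, _ = photostationary_state(no_thermal, true_phis, mono_340, geometry)
        fa1, _ = photostationary_state(fast_thermal, true_phis, mono_340, geometry)
        assert fa1 > fa0


class TestDutyCycleClock:
    def test_identity_without_dead_time(self):
        wall = np.arange(0.0, 301.0, 30.0)
        np.testing.assert_array_equal(effective_irradiation_times(wall), wall)

    def test_dead_time_accumulates_linearly(self):
        wall = np.arange(0.0, 301.0, 30.0)
        eff = effective_irradiation_times(wall, dead_time_per_cycle=0.5)
        np.testing.assert_allclose(eff, wall - 0.5 * np.arange(wall.size))

    def test_excessive_dead_time_rejected(self):
        wall = np.arange(0.0, 301.0, 30.0)
        with pytest.raises(ValueError, match="dead time"):
            effective_irradiation_times(wall, dead_time_per_cycle=31.0)
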