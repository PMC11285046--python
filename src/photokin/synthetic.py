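"""Synthetic fixtures with known ground truth.

Generates azobenzene-like photoswitch systems (Gaussian absorption bands),
Gaussian LED emission profiles, noisy in-operando absorbance time series and
drifting thermopile power logs, so the whole determination pipeline can be
exercised and validated without instruments or downloaded data.

The default preset mirrors the reference experiment: a stable isomer with a
strong pi->pi* band near 320 nm and a weak n->pi* band near 440 nm, a
metastable isomer with bands near 240/280 nm and a slightly stronger n->pi*
band, thermal back-isomerization at 7.2e-7 s^-1 (20 C), true quantum yields
(0.16, 0.38), a 3.00 mL sample in a 1 cm cuvette at a starting absorbance of
~0.9 in the pi->pi* band, 1 h of irradiation with one spectrum every 30 s,
and ~1 mW of 340 nm light (photon flux ~1.7e15 s^-1).

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import photon_energy
from .kinetics import (
    ExperimentGeometry,
    KineticState,
    PhotoswitchSystem,
    QuantumYields,
    SimulationResult,
    simulate,
)
from .photonflux import IrradiationSource, PowerTrace
from .spectra import SpectralTimeSeries, Spectrum

__all__ = [
    "ToySwitchSpec",
    "AZOBENZENE_LIKE",
    "DEFAULT_SCHEDULE",
    "make_toy_switch",
    "make_led_profile",
    "simulate_noisy_experiment",
    "make_power_trace",
    "default_experiment",
]

#: (center nm, 1-sigma width nm, height M^-1 cm^-1) Gaussian bands
Band = tuple[float, float, float]


@dataclass(frozen=True)
class ToySwitchSpec:
    """Recipe for a two-isomer model photoswitch built from Gaussian bands."""

    bands_A: tuple[Band, ...]
    bands_B: tuple[Band, ...]
    k_BA: float = 7.2e-7
    true_phis: QuantumYields = QuantumYields(0.16, 0.38)
    wl_min: float = 200.0
    wl_max: float = 600.0
    wl_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for bands in (self.bands_A, self.bands_B):
            for center, width, height in bands:
                if width <= 0:
                    raise ValueError("band widths must be positive")
                if height < 0:
                    raise ValueError("band heights must be non-negative")


#: azobenzene-like preset: strong 320 nm + weak 440 nm for the stable isomer,
#: 240/280 nm bands and a stronger 440 nm band for the metastable isomer
AZOBENZENE_LIKE = ToySwitchSpec(
    bands_A=((320.0, 30.0, 22000.0), (440.0, 30.0, 450.0)),
    bands_B=((240.0, 15.0, 8000.0), (280.0, 25.0, 5000.0), (440.0, 35.0, 1250.0)),
)

#: 1 h of irradiation, one spectrum every 30 s
DEFAULT_SCHEDULE = np.arange(0.0, 3601.0, 30.0)


def _gaussian_sum(grid: np.ndarray, bands: tuple[Band, ...]) -> np.ndarray:
    vals = np.zeros_like(grid)
    for center, width, height in bands:
        vals += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return vals


def make_toy_switch(spec: ToySwitchSpec = AZOBENZENE_LIKE) -> PhotoswitchSystem:
    """Build a PhotoswitchSystem with Gaussian-band molar absorptivities."""
    grid = np.arange(spec.wl_min, spec.wl_max + spec.wl_step / 2, spec.wl_step)
    eps_A = Spectrum(
        grid, _gaussian_sum(grid, spec.bands_A), kind="molar_absorptivity",
        label="eps_A (stable isomer)",
    )
    eps_B = Spectrum(
        grid, _gaussian_sum(grid, spec.bands_B), kind="molar_absorptivity",
        label="eps_B (metastable isomer)",
    )
    return PhotoswitchSystem(eps_A=eps_A, eps_B=eps_B, k_BA=spec.k_BA)


def make_led_profile(
    center: float, fwhm: float, rel_floor: float = 1e-4, n_points: int = 161
) -> Spectrum:
    """Gaussian LED emission profile, photon-normalised (trapezoid integral 1).

    The profile is built on its own grid spanning the region where the
    intensity exceeds ``rel_floor`` of the peak; an ``fwhm`` at or below the
    numerical resolution degenerates gracefully into a narrow spike, which
    reproduces the monochromatic limit.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half_span = sigma * np.sqrt(-2.0 * np.log(rel_floor))
    grid = np.linspace(center - half_span, center + half_span, n_points)
    if grid[0] <= 0:
        raise ValueError("LED profile extends to non-positive wavelengths")
    vals = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    vals[vals < rel_floor] = 0.0
    integral = float(np.trapezoid(vals, grid))
    return Spectrum(
        grid, vals / integral, kind="emission", label=f"LED {center:g} nm"
    )


@dataclass(frozen=True)
class SyntheticExperiment:
    """A complete simulated determination with its ground truth."""

    series: SpectralTimeSeries
    truth: SimulationResult
    system: PhotoswitchSystem
    source: IrradiationSource
    geometry: ExperimentGeometry
    initial_state: KineticState
    true_phis: QuantumYields


def simulate_noisy_experiment(
    system: PhotoswitchSystem,
    true_phis: QuantumYields,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    schedule=DEFAULT_SCHEDULE,
    noise_sd: float = 0.002,
    seed: int = 0,
    initial_state: KineticState | None = None,
    wavelengths=None,
    heteroscedastic: bool = False,
) -> tuple[SpectralTimeSeries, SimulationResult]:
    """Simulate an in-operando absorbance record with additive noise.

    Returns the noisy :class:`SpectralTimeSeries` together with the noiseless
    ground-truth trajectory.  Noise is i.i.d. Gaussian in absorbance
    (sd ``noise_sd``); with ``heteroscedastic=True`` the sd scales as
    sqrt(1 + Abs) to mimic shot-noise growth.  ``noise_sd = 0`` returns the
    model exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(schedule, dtype=float)
    if initial_state is None:
        initial_state = default_initial_state(system)
    if wavelengths is None:
        wavelengths = system.eps_A.wavelengths
    truth = simulate(system, true_phis, source, geometry, initial_state, times)
    clean = truth.absorbance_at(np.asarray(wavelengths, dtype=float))
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        noisy = clean.copy()
    else:
        scale = noise_sd * (np.sqrt(1.0 + clean) if heteroscedastic else 1.0)
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * scale
    series = SpectralTimeSeries(
        times=times,
        wavelengths=np.asarray(wavelengths, dtype=float),
        absorbance=noisy,
        label=f"synthetic (seed={seed})",
    )
    return series, truth


def make_power_trace(
    p_true: float,
    baseline_coeffs=(5e-4, 0.0),
    noise_sd: float = 0.0,
    duration: float = 180.0,
    dt: float = 0.5,
    on_interval: tuple[float, float] = (60.0, 120.0),
    seed: int = 0,
) -> PowerTrace:
    """Synthetic thermopile log: polynomial drift + LED step + Gaussian noise.

    ``baseline_coeffs`` are polynomial coefficients in W (constant first)
    evaluated in time centred mid-trace, mimicking slow thermal drift of the
    sensor; ``p_true`` W is added during ``on_interval``.
    """
    if p_true < 0:
        raise ValueError("p_true must be non-negative")
    times = np.arange(0.0, duration + dt / 2, dt)
    t0 = times.mean()
    baseline = np.polynomial.polynomial.polyval(times - t0, np.asarray(baseline_coeffs))
    power = baseline.copy()
    on = (times >= on_interval[0]) & (times <= on_interval[1])
    power[on] += p_true
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        power = power + rng.normal(0.0, noise_sd, power.shape)
    return PowerTrace(times=times, power=power, on_interval=on_interval)


def default_initial_state(
    system: PhotoswitchSystem, target_absorbance: float = 0.9
) -> KineticState:
    """All-A starting state with the main band's absorbance at ~0.9 (1 cm)."""
    peak_eps = float(np.max(system.eps_A.values))
    if peak_eps <= 0:
        raise ValueError("eps_A is identically zero; cannot set a starting absorbance")
    return KineticState(conc_A=target_absorbance / peak_eps, conc_B=0.0)


def default_experiment(
    noise_sd: float = 0.002,
    seed: int = 0,
    power_W: float = 1.0e-3,
    wavelength_nm: float = 340.0,
    spec: ToySwitchSpec = AZOBENZENE_LIKE,
) -> SyntheticExperiment:
    """The reference-condition synthetic determination in one call.

    1 mW of 340 nm light (q0 ~ 1.7e15 photons/s) on a 3.00 mL, 1 cm sample
    of the azobenzene-like toy switch, 1 h schedule at 30 s sampling.
    """
    system = make_toy_switch(spec)
    q0 = power_W / photon_energy(wavelength_nm)
    source = IrradiationSource(photon_flux=q0, wavelength_nm=wavelength_nm)
    geometry = ExperimentGeometry(volume_L=3.0e-3)
    initial_state = default_initial_state(system)
    series, truth = simulate_noisy_experiment(
        system,
        spec.true_phis,
        source,
        geometry,
        noise_sd=noise_sd,
        seed=seed,
        initial_state=initial_state,
        wavelengths=np.array([wavelength_nm]),
    )
    return SyntheticExperiment(
        series=series,
        truth=truth,
        system=system,
        source=source,
        geometry=geometry,
        initial_state=initial_state,
        true_phis=spec.true_phis,
    )
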