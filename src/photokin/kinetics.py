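"""Photokinetic rate equations for a two-state photoswitch and their
numerical integration.

Model
-----
A stable isomer A (e.g. trans-azobenzene) and a metastable isomer B (cis)
interconvert photochemically with quantum yields Phi_AB (forward) and Phi_BA
(backward), while B relaxes thermally to A with first-order rate constant
k_BA.  For monochromatic irradiation with photon flux q0 at wavelength
lambda_exc, with Abs_tot = ([A] eps_A + [B] eps_B) * l the decadic absorbance
along the irradiation path l:

    d[A]/dt = (q0 / (N_A V)) * (1 - 10^-Abs_tot)/Abs_tot
              * (Phi_BA [B] eps_B l  -  Phi_AB [A] eps_A l)  +  k_BA [B]
    d[B]/dt = -d[A]/dt

The factor (1 - 10^-Abs_tot) is the fraction of incident photons absorbed
by the solution; each species captures photons in proportion to its share of
the total absorbance.  For a polychromatic source with photon-normalised
spectral distribution f(lambda) the photochemical term is integrated over
wavelength with per-wavelength absorbed fraction and shares.

Total concentration is conserved exactly: the integrator propagates [A]
alone with [B] = c_tot - [A].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .constants import AVOGADRO
from .photonflux import IrradiationSource
from .spectra import SpectralTimeSeries, Spectrum

__all__ = [
    "PhotoswitchSystem",
    "QuantumYields",
    "ExperimentGeometry",
    "KineticState",
    "SimulationResult",
    "absorbed_fraction",
    "species_photon_share",
    "rate_monochromatic",
    "rate_polychromatic",
    "simulate",
    "photostationary_state",
    "effective_irradiation_times",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhotoswitchSystem:
    """Two isomers' molar absorptivity spectra plus the thermal B->A rate.

    ``eps_A``/``eps_B`` in M^-1 cm^-1; ``k_BA`` in s^-1 (>= 0).
    """

    eps_A: Spectrum
    eps_B: Spectrum
    k_BA: float = 0.0

    def __post_init__(self) -> None:
        if self.k_BA < 0:
            raise ValueError("thermal rate constant k_BA must be >= 0")
        for name, s in (("eps_A", self.eps_A), ("eps_B", self.eps_B)):
            if s.kind != "molar_absorptivity":
                raise ValueError(f"{name} must be a molar_absorptivity spectrum")


@dataclass(frozen=True)
class QuantumYields:
    """Forward (A->B) and backward (B->A) photoisomerization quantum yields."""

    phi_AB: float
    phi_BA: float

    def __post_init__(self) -> None:
        for name, v in (("phi_AB", self.phi_AB), ("phi_BA", self.phi_BA)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ExperimentGeometry:
    """Cuvette geometry: irradiation path, probe path (cm), volume (L).

    Irradiation and probing are perpendicular; the absorbance driving the
    photochemistry uses ``path_irradiation``, reported model absorbance uses
    ``path_probe``.  ``temperature_C`` is metadata only.
    """

    volume_L: float
    path_irradiation: float = 1.0
    path_probe: float = 1.0
    temperature_C: float = 20.0

    def __post_init__(self) -> None:
        if self.volume_L <= 0 or self.path_irradiation <= 0 or self.path_probe <= 0:
            raise ValueError("volume and path lengths must be positive")


@dataclass(frozen=True)
class KineticState:
    """Concentrations of both isomers (M) at a time point (s)."""

    conc_A: float
    conc_B: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_A < 0 or self.conc_B < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def total(self) -> float:
        return self.conc_A + self.conc_B


def absorbed_fraction(abs_total: float) -> float:
    """Fraction of incident photons absorbed: 1 - 10^(-Abs_tot).

    ``abs_total`` is the decadic absorbance along the irradiation path.
    """
    scalar = np.ndim(abs_total) == 0
    a = np.atleast_1d(np.asarray(abs_total, dtype=float))
    if np.any(a < 0):
        raise ValueError("absorbance must be non-negative")
    out = 1.0 - 10.0**(-a)
    return float(out[0]) if scalar else out


def species_photon_share(abs_A, abs_B):
    """Each species' share of the absorbed photons: Abs_X / (Abs_A + Abs_B).

    The photon capture rate of species X is q_X = q0 * share_X * absorbed
    fraction; the two shares sum to one.
    """
    scalar = np.ndim(abs_A) == 0 and np.ndim(abs_B) == 0
    abs_A = np.atleast_1d(np.asarray(abs_A, dtype=float))
    abs_B = np.atleast_1d(np.asarray(abs_B, dtype=float))
    if np.any(abs_A < 0) or np.any(abs_B < 0):
        raise ValueError("absorbances must be non-negative")
    total = abs_A + abs_B
    if np.any(total == 0):
        raise ZeroDivisionError(
            "neither species absorbs at this wavelength: photon shares undefined"
        )
    share_A, share_B = abs_A / total, abs_B / total
    if scalar:
        return float(share_A[0]), float(share_B[0])
    return share_A, share_B


def _rate_factor(x):
    """(1 - 10^-x)/x, continuous through x -> 0 where it tends to ln(10).

    A 3-term series is used below 1e-6 so the analytic switch is seamless
    to machine precision.
    """
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    small = x < 1e-6
    out = np.empty_like(x)
    xs = x[small] * LN10
    out[small] = LN10 * (1.0 - xs / 2.0 + xs**2 / 6.0)
    xl = x[~small]
    out[~small] = (1.0 - 10.0 ** (-xl)) / xl
    return float(out[0]) if scalar else out


def _photo_rate_mono(
    conc_A: float,
    conc_B: float,
    eps_A: float,
    eps_B: float,
    phis: QuantumYields,
    q0: float,
    volume_L: float,
    path_cm: float,
) -> float:
    """Photochemical part of d[A]/dt for a monochromatic source, M s^-1."""
    abs_A = conc_A * eps_A * path_cm
    abs_B = conc_B * eps_B * path_cm
    abs_tot = abs_A + abs_B
    return (
        q0
        / (AVOGADRO * volume_L)
        * _rate_factor(abs_tot)
        * (phis.phi_BA * abs_B - phis.phi_AB * abs_A)
    )


def rate_monochromatic(
    state: KineticState,
    system: PhotoswitchSystem,
    phis: QuantumYields,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
) -> tuple[float, float]:
    """(d[A]/dt, d[B]/dt) in M s^-1 under monochromatic irradiation."""
    if not source.is_monochromatic:
        raise ValueError("source is polychromatic; use rate_polychromatic")
    lam = source.wavelength_nm
    dA = (
        _photo_rate_mono(
            state.conc_A,
            state.conc_B,
            system.eps_A(lam),
            system.eps_B(lam),
            phis,
            source.photon_flux,
            geometry.volume_L,
            geometry.path_irradiation,
        )
        + system.k_BA * state.conc_B
    )
    return dA, -dA


def _poly_grid(system: PhotoswitchSystem, source: IrradiationSource) -> np.ndarray:
    """Emission grid restricted to where both eps spectra are defined."""
    f = source.emission
    lo = max(f.wl_min, system.eps_A.wl_min, system.eps_B.wl_min)
    hi = min(f.wl_max, system.eps_A.wl_max, system.eps_B.wl_max)
    if lo >= hi:
        raise ValueError(
            "no spectral overlap between the source emission and the molar "
            "absorptivity spectra"
        )
    grid = f.wavelengths[(f.wavelengths >= lo) & (f.wavelengths <= hi)]
    if grid.size < 2:
        raise ValueError("fewer than 2 emission grid points overlap the eps spectra")
    return grid


def _photo_rate_poly(
    conc_A: float,
    conc_B: float,
    grid: np.ndarray,
    f_vals: np.ndarray,
    eps_A: np.ndarray,
    eps_B: np.ndarray,
    phis: QuantumYields,
    q0: float,
    volume_L: float,
    path_cm: float,
) -> float:
    abs_A = conc_A * eps_A * path_cm
    abs_B = conc_B * eps_B * path_cm
    integrand = (
        _rate_factor(abs_A + abs_B)
        * (phis.phi_BA * abs_B - phis.phi_AB * abs_A)
        * f_vals
    )
    return q0 / (AVOGADRO * volume_L) * float(np.trapezoid(integrand, grid))


def rate_polychromatic(
    state: KineticState,
    system: PhotoswitchSystem,
    phis: QuantumYields,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    include_thermal: bool = True,
) -> tuple[float, float]:
    """(d[A]/dt, d[B]/dt) with the LED emission spectrum integrated over.

    Trapezoid quadrature of the per-wavelength photochemical rate on the
    emission grid restricted to the molar-absorptivity range.  The thermal
    B->A term is included by default for consistency with the monochromatic
    rate; ``include_thermal=False`` drops it.
    """
    if source.is_monochromatic:
        raise ValueError("source is monochromatic; use rate_monochromatic")
    grid = _poly_grid(system, source)
    f_vals = source.emission(grid)
    dA = _photo_rate_poly(
        state.conc_A,
        state.conc_B,
        grid,
        np.atleast_1d(f_vals),
        np.atleast_1d(system.eps_A(grid)),
        np.atleast_1d(system.eps_B(grid)),
        phis,
        source.photon_flux,
        geometry.volume_L,
        geometry.path_irradiation,
    )
    if include_thermal:
        dA += system.k_BA * state.conc_B
    return dA, -dA


@dataclass(frozen=True)
class SimulationResult:
    """Concentration trajectory plus a probe-path absorbance evaluator."""

    times: np.ndarray
    conc_A: np.ndarray
    conc_B: np.ndarray
    system: PhotoswitchSystem
    geometry: ExperimentGeometry

    def absorbance_at(self, wavelengths) -> np.ndarray:
        """Model probe absorbance, shape (n_times,) or (n_times, n_wl)."""
        scalar = np.ndim(wavelengths) == 0
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        eA = np.atleast_1d(self.system.eps_A(wl))
        eB = np.atleast_1d(self.system.eps_B(wl))
        out = (
            np.outer(self.conc_A, eA) + np.outer(self.conc_B, eB)
        ) * self.geometry.path_probe
        return out[:, 0] if scalar else out

    def to_time_series(self, wavelengths) -> SpectralTimeSeries:
        wl = np.asarray(wavelengths, dtype=float)
        return SpectralTimeSeries(
            times=self.times, wavelengths=wl, absorbance=self.absorbance_at(wl)
        )

    def state_at(self, index: int) -> KineticState:
        return KineticState(
            conc_A=float(self.conc_A[index]),
            conc_B=float(self.conc_B[index]),
            time=float(self.times[index]),
        )


def simulate(
    system: PhotoswitchSystem,
    phis: QuantumYields,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    initial: KineticState,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    include_thermal: bool = True,
) -> SimulationResult:
    """Integrate the rate equations and return the trajectory at ``times``.

    Uses a stiff-capable adaptive integrator (LSODA).  Total concentration is
    conserved exactly by construction ([B] = c_tot - [A]).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")
    c_tot = initial.total

    if source.is_monochromatic:
        lam = source.wavelength_nm
        eA = float(system.eps_A(lam))
        eB = float(system.eps_B(lam))

        def rhs(t, y):
            a = y[0]
            b = c_tot - a
            return [
                _photo_rate_mono(
                    a, b, eA, eB, phis, source.photon_flux,
                    geometry.volume_L, geometry.path_irradiation,
                )
                + system.k_BA * b
            ]

    else:
        grid = _poly_grid(system, source)
        f_vals = np.atleast_1d(source.emission(grid))
        eA_grid = np.atleast_1d(system.eps_A(grid))
        eB_grid = np.atleast_1d(system.eps_B(grid))

        def rhs(t, y):
            a = y[0]
            b = c_tot - a
            dA = _photo_rate_poly(
                a, b, grid, f_vals, eA_grid, eB_grid, phis,
                source.photon_flux, geometry.volume_L, geometry.path_irradiation,
            )
            if include_thermal:
                dA += system.k_BA * b
            return [dA]

    t0 = min(float(times[0]), initial.time)
    sol = solve_ivp(
        rhs,
        (t0, float(times[-1])),
        [initial.conc_A],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else t0
        raise RuntimeError(
            f"ODE integration failed at t={last_t:g} s: {sol.message}"
        )
    conc_A = np.clip(sol.y[0], 0.0, c_tot)
    return SimulationResult(
        times=times,
        conc_A=conc_A,
        conc_B=c_tot - conc_A,
        system=system,
        geometry=geometry,
    )


def photostationary_state(
    system: PhotoswitchSystem,
    phis: QuantumYields,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    total_conc: float = 1e-5,
) -> tuple[float, float]:
    """Stationary isomer fractions (fraction_A, fraction_B) under irradiation.

    Solves d[A]/dt = 0 at fixed total concentration by bracketed root
    finding on fraction_B.  For monochromatic light with k_BA = 0 this
    reproduces the closed form [B]/[A] = (Phi_AB eps_A)/(Phi_BA eps_B).
    When k_BA > 0 the balance point depends on the photon flux, the volume
    and ``total_conc``.
    """
    if total_conc <= 0:
        raise ValueError("total_conc must be positive")

    def dA_dt(frac_B: float) -> float:
        state = KineticState(
            conc_A=total_conc * (1.0 - frac_B), conc_B=total_conc * frac_B
        )
        if source.is_monochromatic:
            return rate_monochromatic(state, system, phis, source, geometry)[0]
        return rate_polychromatic(state, system, phis, source, geometry)[0]

    g0 = dA_dt(0.0)
    g1 = dA_dt(1.0)
    if g0 == 0.0 and g1 == 0.0:
        raise ValueError(
            "no photochemical or thermal flux: photostationary state undefined"
        )
    if g0 == 0.0:  # no forward drive (q0=0, phi_AB=0 or eps_A=0): all-A is stationary
        return 1.0, 0.0
    if g1 == 0.0:
        return 0.0, 1.0
    if g0 > 0 or g1 < 0:
        raise ValueError(
            "no stationary composition in (0, 1) for the given parameters"
        )
    frac_B = brentq(dA_dt, 0.0, 1.0, xtol=1e-14, rtol=1e-15)
    return 1.0 - frac_B, frac_B


def effective_irradiation_times(
    wall_times, dead_time_per_cycle: float = 0.0
) -> np.ndarray:
    """Cumulative LED-on time for a duty-cycled irradiation schedule.

    The LED is switched off for ``dead_time_per_cycle`` seconds around each
    spectrum acquisition; the i-th recorded spectrum (i = 0, 1, ...) has then
    accumulated ``wall_times[i] - i * dead_time_per_cycle`` seconds of actual
    irradiation.  With zero dead time this is the identity.
    """
    wall = np.asarray(wall_times, dtype=float)
    if dead_time_per_cycle < 0:
        raise ValueError("dead time must be non-negative")
    eff = wall - dead_time_per_cycle * np.arange(wall.size)
    if np.any(np.diff(eff) <= 0):
        raise ValueError(
            "dead time exceeds the spacing between spectra: effective "
            "irradiation times are not increasing"
        )
    return eff
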