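"""Thermopile power logs to photon flux.

The radiant power delivered to the cuvette is measured with a calibrated
thermopile sensor instead of a chemical actinometer.  The processing chain
mirrors standard practice for drifting thermal sensors:

1. fit a low-order polynomial baseline to the LED-off segments of the log
   and subtract it from the whole trace;
2. average the LED-on segment (after a settle time) to a mean power and
   sample standard deviation;
3. correct for transmission losses through the cuvette/jacket optics,
   attributing a configurable fraction (default half) of the total measured
   loss to light that never reached the sample;
4. combine repeated determinations by inverse-variance weighting;
5. convert watts to photons per second, either at a single excitation
   wavelength or by integrating a measured LED emission spectrum converted
   to the photon basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import AVOGADRO, NM_TO_M, PLANCK_H, SPEED_OF_LIGHT, photon_energy
from .spectra import Spectrum

__all__ = [
    "PowerTrace",
    "PowerResult",
    "IrradiationSource",
    "InsufficientBaselineError",
    "subtract_baseline",
    "average_on_power",
    "correct_transmission_loss",
    "weighted_mean_power",
    "photon_flux",
    "detect_on_interval",
    "read_power_trace",
]


class InsufficientBaselineError(ValueError):
    """Too few LED-off samples to fit the requested baseline polynomial."""


@dataclass(frozen=True)
class PowerTrace:
    """Timestamped thermopile readings with the LED-on interval marked.

    ``times`` in seconds (strictly increasing), ``power`` in watts,
    ``on_interval = (t_start, t_end)`` in seconds within the trace.
    """

    times: np.ndarray
    power: np.ndarray
    on_interval: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "power", p)
        object.__setattr__(
            self, "on_interval", (float(self.on_interval[0]), float(self.on_interval[1]))
        )
        if t.ndim != 1 or t.shape != p.shape:
            raise ValueError("times and power must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(p)):
            raise ValueError("power values must be finite")
        t0, t1 = self.on_interval
        if not (t[0] <= t0 < t1 <= t[-1]):
            raise ValueError(
                f"on_interval {self.on_interval} must lie within "
                f"[{t[0]:g}, {t[-1]:g}] with t_start < t_end"
            )

    @property
    def on_mask(self) -> np.ndarray:
        t0, t1 = self.on_interval
        return (self.times >= t0) & (self.times <= t1)


@dataclass(frozen=True)
class PowerResult:
    """An averaged power determination: mean +/- std (W) over n samples."""

    mean_power: float
    std_power: float
    n_samples: int
    correction_applied: bool = False

    def __post_init__(self) -> None:
        if self.std_power < 0:
            raise ValueError("std_power must be non-negative")


@dataclass(frozen=True)
class IrradiationSource:
    """Excitation source: photon flux plus spectral mode.

    ``photon_flux`` (q0) is in photons s^-1.  Exactly one of ``wavelength_nm``
    (monochromatic line) or ``emission`` (photon-normalised spectral
    distribution f(lambda), integral 1 by the trapezoid rule) is set.
    """

    photon_flux: float
    wavelength_nm: float | None = None
    emission: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.photon_flux < 0:
            raise ValueError("photon flux must be non-negative")
        if (self.wavelength_nm is None) == (self.emission is None):
            raise ValueError("set exactly one of wavelength_nm or emission")
        if self.wavelength_nm is not None and self.wavelength_nm <= 0:
            raise ValueError("excitation wavelength must be positive")
        if self.emission is not None:
            f = self.emission
            integral = float(np.trapezoid(f.values, f.wavelengths))
            if abs(integral - 1.0) > 1e-9:
                raise ValueError(
                    f"emission distribution must integrate to 1 "
                    f"(trapezoid rule); got {integral:.12g}"
                )

    @property
    def is_monochromatic(self) -> bool:
        return self.wavelength_nm is not None

    def scaled(self, factor: float) -> "IrradiationSource":
        """Same spectral mode with the photon flux multiplied by ``factor``."""
        return replace(self, photon_flux=self.photon_flux * factor)


def subtract_baseline(trace: PowerTrace, degree: int = 1) -> PowerTrace:
    """Remove a polynomial background fitted to the LED-off samples.

    The polynomial (default degree 1) is fit to all samples outside
    ``on_interval`` — before LED-on and, when recorded, after LED-off — and
    subtracted from the entire trace, so the off-segments scatter around zero
    and the on-segment reads the net LED power.
    """
    if not 0 <= degree <= 3:
        raise ValueError("baseline degree must be between 0 and 3")
    off = ~trace.on_mask
    n_off = int(off.sum())
    if n_off < degree + 2:
        raise InsufficientBaselineError(
            f"need at least {degree + 2} LED-off samples for a degree-{degree} "
            f"baseline, found {n_off}"
        )
    # center time for conditioning
    t0 = trace.times.mean()
    coeffs = np.polynomial.polynomial.polyfit(
        trace.times[off] - t0, trace.power[off], degree
    )
    baseline = np.polynomial.polynomial.polyval(trace.times - t0, coeffs)
    return PowerTrace(trace.times, trace.power - baseline, trace.on_interval)


def average_on_power(corrected: PowerTrace, settle_time: float = 5.0) -> PowerResult:
    """Mean and sample standard deviation of the LED-on segment.

    The first ``settle_time`` seconds after LED-on are discarded to skip the
    thermopile's thermal rise.
    """
    t0, t1 = corrected.on_interval
    if t1 - t0 <= settle_time:
        raise ValueError(
            f"on_interval duration {t1 - t0:g} s does not exceed "
            f"settle_time {settle_time:g} s"
        )
    window = (corrected.times >= t0 + settle_time) & (corrected.times <= t1)
    n = int(window.sum())
    if n == 0:
        raise ValueError("no samples in the averaging window after settle_time")
    vals = corrected.power[window]
    mean = float(vals.mean())
    std = float(vals.std(ddof=1)) if n > 1 else 0.0
    return PowerResult(mean_power=mean, std_power=std, n_samples=n)


def correct_transmission_loss(
    P_bare: PowerResult,
    P_through: PowerResult,
    loss_fraction_at_sample: float = 0.5,
) -> PowerResult:
    """Power at the sample from bare-beam and through-optics determinations.

    Light lost between collimator and detector is split between losses before
    and after the cuvette; the fraction attributed to the sample side
    (default one half) is removed from the bare power:

        P_sample = P_bare - f * (P_bare - P_through)
                 = (1 - f) * P_bare + f * P_through

    Uncertainties combine in quadrature with the same (1-f, f) weights.
    """
    f = loss_fraction_at_sample
    if not 0.0 <= f <= 1.0:
        raise ValueError("loss_fraction_at_sample must be in [0, 1]")
    if P_through.mean_power > P_bare.mean_power:
        raise ValueError(
            f"through-optics power ({P_through.mean_power:g} W) exceeds bare power "
            f"({P_bare.mean_power:g} W): physically inconsistent measurement pair"
        )
    if P_through.mean_power < 0:
        raise ValueError("through-optics power must be non-negative")
    mean = (1.0 - f) * P_bare.mean_power + f * P_through.mean_power
    std = math.hypot((1.0 - f) * P_bare.std_power, f * P_through.std_power)
    return PowerResult(
        mean_power=mean,
        std_power=std,
        n_samples=min(P_bare.n_samples, P_through.n_samples),
        correction_applied=True,
    )


def weighted_mean_power(results: list[PowerResult]) -> PowerResult:
    """Inverse-variance-weighted mean of repeated power determinations.

    Weights are 1/std^2; the combined uncertainty is sqrt(1/sum(w)).  With all
    uncertainties zero the plain mean is returned; a mix of zero and non-zero
    uncertainties is ambiguous and rejected.
    """
    if not results:
        raise ValueError("need at least one power result")
    if len(results) == 1:
        return results[0]
    stds = np.array([r.std_power for r in results])
    means = np.array([r.mean_power for r in results])
    if np.all(stds == 0):
        return PowerResult(
            mean_power=float(means.mean()),
            std_power=0.0,
            n_samples=sum(r.n_samples for r in results),
            correction_applied=any(r.correction_applied for r in results),
        )
    if np.any(stds == 0):
        raise ValueError(
            "mix of zero and non-zero power uncertainties: inverse-variance "
            "weights are undefined; supply explicit uncertainties for all entries"
        )
    w = 1.0 / stds**2
    return PowerResult(
        mean_power=float(np.sum(w * means) / np.sum(w)),
        std_power=float(np.sqrt(1.0 / np.sum(w))),
        n_samples=sum(r.n_samples for r in results),
        correction_applied=any(r.correction_applied for r in results),
    )


def photon_flux(
    P_sample: PowerResult,
    wavelength_nm: float | None = None,
    emission: Spectrum | None = None,
    emission_in_photon_basis: bool = False,
) -> IrradiationSource:
    """Convert radiant power to a photon flux.

    Monochromatic mode (``wavelength_nm`` given):

        q0 = P * lambda / (h * c)     [photons s^-1]

    Polychromatic mode (``emission`` given): the measured relative emission
    intensity g(lambda) is taken to be on the power basis (J s^-1 nm^-1,
    relative), converted per-wavelength to a photon-rate density
    phi(lambda) ~ g(lambda) * lambda, and scaled so the total radiant power
    integral(phi * h c / lambda) equals ``P_sample.mean_power``.  Then
    q0 = integral(phi d lambda) and f = phi / q0.  Spectrometers that already
    report photon counts can set ``emission_in_photon_basis=True`` to skip
    the lambda-weighting.
    """
    if (wavelength_nm is None) == (emission is None):
        raise ValueError("give exactly one of wavelength_nm or emission")
    P = P_sample.mean_power
    if P < 0:
        raise ValueError("power must be non-negative")

    if wavelength_nm is not None:
        q0 = P / photon_energy(wavelength_nm)
        return IrradiationSource(photon_flux=q0, wavelength_nm=wavelength_nm)

    g = emission.values
    wl = emission.wavelengths
    if np.all(g == 0):
        raise ValueError("emission spectrum is identically zero")
    phi_shape = g.copy() if emission_in_photon_basis else g * wl
    # photon energies per bin, J
    e_photon = PLANCK_H * SPEED_OF_LIGHT / (wl * NM_TO_M)
    power_integral = float(np.trapezoid(phi_shape * e_photon, wl))
    if P == 0 or power_integral == 0:
        return IrradiationSource(
            photon_flux=0.0,
            emission=_photon_normalise(wl, phi_shape, emission.label),
        )
    scale = P / power_integral
    phi = phi_shape * scale
    q0 = float(np.trapezoid(phi, wl))
    return IrradiationSource(
        photon_flux=q0, emission=_photon_normalise(wl, phi, emission.label)
    )


def _photon_normalise(wl: np.ndarray, phi: np.ndarray, label: str) -> Spectrum:
    integral = float(np.trapezoid(phi, wl))
    if integral <= 0:
        raise ValueError("cannot normalise an all-zero emission distribution")
    return Spectrum(wl, phi / integral, kind="emission", label=label or "f(lambda)")


def detect_on_interval(
    times: np.ndarray, power: np.ndarray, threshold_sigma: float = 5.0
) -> tuple[float, float]:
    """Heuristic LED-on window: longest contiguous run above baseline noise.

    The baseline level and scatter are estimated from the lower half of the
    power values; samples above baseline + ``threshold_sigma`` * scatter form
    candidate on-runs.  Raises if no unambiguous run is found.
    """
    times = np.asarray(times, dtype=float)
    power = np.asarray(power, dtype=float)
    lower = np.sort(power)[: max(2, power.size // 2)]
    base, noise = float(lower.mean()), float(lower.std(ddof=1))
    if noise == 0:
        noise = max(1e-12, 1e-9 * max(abs(base), 1.0))
    above = power > base + threshold_sigma * noise
    if not above.any():
        raise ValueError("no LED-on segment detected above the baseline noise")
    # longest contiguous run of True
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, above.size - 1))
    runs.sort(key=lambda r: times[r[1]] - times[r[0]], reverse=True)
    if len(runs) > 1 and (
        times[runs[1][1]] - times[runs[1][0]] > 0.5 * (times[runs[0][1]] - times[runs[0][0]])
    ):
        raise ValueError(
            "ambiguous LED-on detection (two comparable segments); "
            "supply the on-interval explicitly"
        )
    i0, i1 = runs[0]
    return float(times[i0]), float(times[i1])


def read_power_trace(
    path: str, on_interval: tuple[float, float] | None = None
) -> PowerTrace:
    """Read a power log: delimited text with columns ``time_s,power_W``.

    A three-column ``timestamp,power,unit`` export is also accepted; readings
    in mW or uW are normalised to W.  If ``on_interval`` is omitted it is
    auto-detected with :func:`detect_on_interval`.
    """
    import csv as _csv

    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    delim = "\t" if lines[0].count("\t") >= lines[0].count(",") else ","
    header = [c.strip().lower() for c in next(_csv.reader([lines[0]], delimiter=delim))]
    times, powers = [], []
    unit_scale = {"w": 1.0, "mw": 1e-3, "uw": 1e-6, "µw": 1e-6}
    for i, ln in enumerate(lines[1:], start=2):
        cells = next(_csv.reader([ln], delimiter=delim))
        try:
            t, p = float(cells[0]), float(cells[1])
        except (ValueError, IndexError):
            raise ValueError(f"{path}: cannot parse row {i}: {ln.strip()!r}") from None
        if len(header) >= 3 and header[2] == "unit" and len(cells) >= 3:
            p *= unit_scale.get(cells[2].strip().lower(), 1.0)
        times.append(t)
        powers.append(p)
    t_arr, p_arr = np.asarray(times), np.asarray(powers)
    if on_interval is None:
        on_interval = detect_on_interval(t_arr, p_arr)
    return PowerTrace(t_arr, p_arr, on_interval)
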