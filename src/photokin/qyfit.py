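"""Inverse problem: fit the isomerization quantum yields to measured
absorbance-vs-time data and propagate the power-measurement uncertainty.

The pair (Phi_A->B, Phi_B->A) is estimated by bounded Levenberg-Marquardt
least squares (lmfit) on the residual between the measured absorbance at the
observation wavelength(s) and the absorbance modelled by integrating the
photokinetic rate equations.  Fit standard errors come from the linearised
covariance at the optimum.

The dominant experimental uncertainty is the LED power, which the fit
standard errors do not see.  It is propagated by refitting at the lower and
upper power limits P -/+ dP; each refit carries its own fit standard error,
which widens the bounds:

    Phi_min = min over refits (Phi)  -  its fit SE
    Phi_max = max over refits (Phi)  +  its fit SE
    dPhi    = max(|Phi - Phi_min|, |Phi - Phi_max|)

Replicate determinations are combined by inverse-variance weighting with a
weighted sample standard deviation as the reported spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .kinetics import (
    ExperimentGeometry,
    KineticState,
    PhotoswitchSystem,
    QuantumYields,
    simulate,
)
from .photonflux import IrradiationSource, PowerResult

__all__ = [
    "QYFitResult",
    "ReplicateSummary",
    "IdentifiabilityError",
    "fit_quantum_yields",
    "propagate_power_uncertainty",
    "determine_quantum_yields",
    "aggregate_replicates",
]


class IdentifiabilityError(RuntimeError):
    """The data carry no information on one or both quantum yields."""


@dataclass(frozen=True)
class QYFitResult:
    """Fitted quantum yields with their uncertainty budget.

    ``se_*`` are linearised fit standard errors; ``phi_*_min``/``phi_*_max``
    and ``delta_phi_*`` are filled by the power-propagation step (NaN until
    then).  ``warnings`` collects identifiability diagnostics.
    """

    phi_AB: float
    phi_BA: float
    se_AB: float
    se_BA: float
    rss: float
    n_points: int
    converged: bool
    phi_AB_min: float = math.nan
    phi_AB_max: float = math.nan
    phi_BA_min: float = math.nan
    phi_BA_max: float = math.nan
    delta_phi_AB: float = math.nan
    delta_phi_BA: float = math.nan
    warnings: tuple[str, ...] = ()

    @property
    def phis(self) -> QuantumYields:
        return QuantumYields(self.phi_AB, self.phi_BA)

    def summary_lines(self) -> list[str]:
        out = [
            f"phi_AB={self.phi_AB:.6g}",
            f"se_AB={self.se_AB:.3g}",
            f"phi_BA={self.phi_BA:.6g}",
            f"se_BA={self.se_BA:.3g}",
            f"rss={self.rss:.6g}",
            f"n_points={self.n_points}",
            f"converged={self.converged}",
        ]
        if not math.isnan(self.delta_phi_AB):
            out += [
                f"phi_AB_min={self.phi_AB_min:.6g}",
                f"phi_AB_max={self.phi_AB_max:.6g}",
                f"delta_phi_AB={self.delta_phi_AB:.3g}",
                f"phi_BA_min={self.phi_BA_min:.6g}",
                f"phi_BA_max={self.phi_BA_max:.6g}",
                f"delta_phi_BA={self.delta_phi_BA:.3g}",
            ]
        for w in self.warnings:
            out.append(f"warning={w}")
        return out


@dataclass(frozen=True)
class ReplicateSummary:
    """Inverse-variance-weighted combination of replicate determinations."""

    phi_weighted_mean: float
    sample_std: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.sample_std < 0:
            raise ValueError("sample_std must be non-negative")


def _check_identifiability(
    system: PhotoswitchSystem,
    source: IrradiationSource,
    initial_state: KineticState,
) -> list[str]:
    warnings = []
    if source.photon_flux == 0:
        warnings.append(
            "photon flux is zero: the data are dark kinetics and carry no "
            "information on either quantum yield"
        )
        return warnings
    if source.is_monochromatic:
        lam = [source.wavelength_nm]
        weight = [1.0]
    else:
        lam = source.emission.wavelengths
        weight = source.emission.values
    eA = np.atleast_1d(system.eps_A(np.clip(lam, system.eps_A.wl_min, system.eps_A.wl_max)))
    eB = np.atleast_1d(system.eps_B(np.clip(lam, system.eps_B.wl_min, system.eps_B.wl_max)))
    w = np.atleast_1d(np.asarray(weight, dtype=float))
    if float(np.sum(eA * w)) == 0.0:
        warnings.append(
            "species A does not absorb the excitation light: phi_AB is "
            "unconstrained by these data"
        )
    if float(np.sum(eB * w)) == 0.0:
        warnings.append(
            "species B does not absorb the excitation light: phi_BA is "
            "unconstrained by these data"
        )
    return warnings


def fit_quantum_yields(
    times,
    absorbance,
    system: PhotoswitchSystem,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    initial_state: KineticState,
    observation_wavelengths=None,
    init_guess: QuantumYields = QuantumYields(0.3, 0.3),
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0)),
    sigma=None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> QYFitResult:
    """Fit (Phi_AB, Phi_BA) to measured absorbance-vs-time.

    Parameters
    ----------
    times, absorbance
        Irradiation times (s) and the measured probe absorbance: a 1-D array
        for a single observation wavelength or a 2-D array of shape
        (n_times, n_wavelengths) for a joint multi-wavelength fit.
    observation_wavelengths
        Defaults to the excitation wavelength (monochromatic source) — the
        absorbance at the irradiation wavelength is the most sensitive probe
        of the conversion.  Required for a polychromatic source.
    sigma
        Optional per-point absorbance uncertainties for weighted residuals.

    Returns
    -------
    QYFitResult with fit standard errors from the linearised covariance; the
    power-propagated bounds are NaN until
    :func:`propagate_power_uncertainty` fills them.
    """
    times = np.asarray(times, dtype=float)
    data = np.asarray(absorbance, dtype=float)
    if times.size < 5:
        raise ValueError("need at least 5 time points to fit two quantum yields")
    if observation_wavelengths is None:
        if not source.is_monochromatic:
            raise ValueError(
                "observation_wavelengths must be given for a polychromatic source"
            )
        observation_wavelengths = source.wavelength_nm
    obs_wl = np.atleast_1d(np.asarray(observation_wavelengths, dtype=float))
    if data.ndim == 1:
        data = data[:, None]
    if data.shape != (times.size, obs_wl.size):
        raise ValueError(
            f"absorbance shape {data.shape} does not match "
            f"(n_times={times.size}, n_wavelengths={obs_wl.size})"
        )
    if sigma is not None:
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), data.shape)

    warnings = _check_identifiability(system, source, initial_state)
    if any("either quantum yield" in w for w in warnings):
        raise IdentifiabilityError(warnings[0])

    params = lmfit.Parameters()
    params.add("phi_AB", value=init_guess.phi_AB, min=bounds[0][0], max=bounds[0][1])
    params.add("phi_BA", value=init_guess.phi_BA, min=bounds[1][0], max=bounds[1][1])

    def residual(p):
        phis = QuantumYields(p["phi_AB"].value, p["phi_BA"].value)
        model = simulate(
            system, phis, source, geometry, initial_state, times, rtol=rtol, atol=atol
        ).absorbance_at(obs_wl)
        res = model - data
        if sigma is not None:
            res = res / sigma
        return res.ravel()

    result = lmfit.minimize(residual, params, method="leastsq")
    phi_AB = float(result.params["phi_AB"].value)
    phi_BA = float(result.params["phi_BA"].value)

    def _se(name: str) -> float:
        err = result.params[name].stderr
        return float(err) if err is not None else math.nan

    se_AB, se_BA = _se("phi_AB"), _se("phi_BA")
    if math.isnan(se_AB) and "phi_AB is" not in " ".join(warnings):
        warnings.append("fit covariance unavailable for phi_AB (flat likelihood?)")
    if math.isnan(se_BA) and "phi_BA is" not in " ".join(warnings):
        warnings.append("fit covariance unavailable for phi_BA (flat likelihood?)")

    raw_res = residual(result.params)
    return QYFitResult(
        phi_AB=phi_AB,
        phi_BA=phi_BA,
        se_AB=se_AB,
        se_BA=se_BA,
        rss=float(np.sum(raw_res**2)),
        n_points=int(data.size),
        converged=bool(result.success),
        warnings=tuple(warnings),
    )


def propagate_power_uncertainty(
    central: QYFitResult,
    times,
    absorbance,
    system: PhotoswitchSystem,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    initial_state: KineticState,
    power: PowerResult,
    observation_wavelengths=None,
    bound_multiple: float = 1.0,
    **fit_kwargs,
) -> QYFitResult:
    """Widen a fitted yield pair by the power-measurement uncertainty.

    Refits at the power limits P -/+ ``bound_multiple`` * dP (implemented by
    scaling the photon flux, which is linear in power).  Because the yields
    vary roughly inversely with the assumed photon flux, the lower power
    limit gives the upper yield estimate and vice versa; the per-yield
    min/max over the two refits, widened by each refit's own fit standard
    error, gives Phi_min and Phi_max, and the total per-yield uncertainty is
    max(|Phi - Phi_min|, |Phi - Phi_max|).
    """
    if power.mean_power <= 0:
        raise ValueError("power mean must be positive to form relative bounds")
    rel = bound_multiple * power.std_power / power.mean_power
    fit_kwargs = dict(fit_kwargs)
    fit_kwargs.pop("init_guess", None)  # bound refits start from the central fit
    refits = {}
    for name, factor in (("low", 1.0 - rel), ("high", 1.0 + rel)):
        if factor <= 0:
            raise ValueError(
                f"power uncertainty too large: {name}-power bound is non-positive"
            )
        try:
            refits[name] = fit_quantum_yields(
                times,
                absorbance,
                system,
                source.scaled(factor),
                geometry,
                initial_state,
                observation_wavelengths=observation_wavelengths,
                init_guess=central.phis,
                **fit_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with bound context
            raise RuntimeError(
                f"refit at the {name}-power bound failed: {exc}"
            ) from exc

    def _bounds(attr: str, se_attr: str, phi: float) -> tuple[float, float, float]:
        cands = [(getattr(r, attr), getattr(r, se_attr)) for r in refits.values()]
        ses = [0.0 if math.isnan(se) else se for _, se in cands]
        lo = min(v - se for (v, _), se in zip(cands, ses))
        hi = max(v + se for (v, _), se in zip(cands, ses))
        lo = min(lo, phi)
        hi = max(hi, phi)
        return lo, hi, max(abs(phi - lo), abs(phi - hi))

    ab_min, ab_max, d_ab = _bounds("phi_AB", "se_AB", central.phi_AB)
    ba_min, ba_max, d_ba = _bounds("phi_BA", "se_BA", central.phi_BA)
    return replace(
        central,
        phi_AB_min=ab_min,
        phi_AB_max=ab_max,
        phi_BA_min=ba_min,
        phi_BA_max=ba_max,
        delta_phi_AB=d_ab,
        delta_phi_BA=d_ba,
    )


def determine_quantum_yields(
    times,
    absorbance,
    system: PhotoswitchSystem,
    source: IrradiationSource,
    geometry: ExperimentGeometry,
    initial_state: KineticState,
    power: PowerResult | None = None,
    observation_wavelengths=None,
    bound_multiple: float = 1.0,
    **fit_kwargs,
) -> QYFitResult:
    """Central fit plus (when ``power`` is given) power-uncertainty bounds."""
    central = fit_quantum_yields(
        times,
        absorbance,
        system,
        source,
        geometry,
        initial_state,
        observation_wavelengths=observation_wavelengths,
        **fit_kwargs,
    )
    if power is None:
        return central
    return propagate_power_uncertainty(
        central,
        times,
        absorbance,
        system,
        source,
        geometry,
        initial_state,
        power,
        observation_wavelengths=observation_wavelengths,
        bound_multiple=bound_multiple,
        **fit_kwargs,
    )


def aggregate_replicates(phis, delta_phis) -> ReplicateSummary:
    """Combine replicate yield determinations by inverse-variance weighting.

    Weights are 1/dPhi^2.  The reported spread for n >= 2 is the weighted
    sample standard deviation

        sqrt( sum(w_i (Phi_i - Phi_bar)^2) / (((n-1)/n) * sum(w_i)) )

    For a single replicate the value is returned with its own dPhi as spread.
    """
    phis = np.asarray(phis, dtype=float)
    dphis = np.asarray(delta_phis, dtype=float)
    if phis.shape != dphis.shape or phis.ndim != 1 or phis.size == 0:
        raise ValueError("phis and delta_phis must be equal-length 1-D sequences")
    n = phis.size
    if n == 1:
        if dphis[0] <= 0:
            raise ValueError("a single replicate needs delta_phi > 0")
        return ReplicateSummary(float(phis[0]), float(dphis[0]), 1)
    if np.any(dphis == 0):
        raise ValueError(
            "zero delta_phi among replicates: inverse-variance weights are "
            "undefined; supply explicit uncertainties"
        )
    w = 1.0 / dphis**2
    mean = float(np.sum(w * phis) / np.sum(w))
    var = float(np.sum(w * (phis - mean) ** 2) / (((n - 1) / n) * np.sum(w)))
    return ReplicateSummary(mean, math.sqrt(var), int(n))
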