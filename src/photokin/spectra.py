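"""Spectrum containers, interpolation, delimited-text I/O and two-component
mixture decomposition.

A :class:`Spectrum` is a wavelength-indexed vector of values carrying a unit
tag (``absorbance``, ``molar_absorptivity`` or ``emission``).  A
:class:`SpectralTimeSeries` is an ordered stack of absorbance spectra on one
shared wavelength grid, time-stamped in seconds since the first LED-on.

The mixture decomposition solves the two-component Beer-Lambert identity

    Abs_obs(lambda) = c * Abs_A(lambda) + (1 - c) * Abs_B(lambda)

for the mole fraction ``c`` of component A by closed-form one-parameter
linear least squares.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "SpectralTimeSeries",
    "SpectrumFormatError",
    "WavelengthRangeError",
    "DegenerateSpectraError",
    "interpolate",
    "decompose_mixture",
    "read_spectrum",
    "write_spectrum",
    "read_time_series",
    "write_time_series",
]

#: unit tags accepted in file headers, mapped to canonical kind names
_UNIT_TO_KIND = {
    "absorbance": "absorbance",
    "M-1cm-1": "molar_absorptivity",
    "counts": "emission",
}
_KIND_TO_UNIT = {v: k for k, v in _UNIT_TO_KIND.items()}


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files (missing header, bad cells, ...)."""


class WavelengthRangeError(ValueError):
    """Raised when a query wavelength falls outside a spectrum's grid."""


class DegenerateSpectraError(ValueError):
    """Raised when the two pure spectra cannot be distinguished in a fit range."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed spectrum.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing wavelengths in nm, all positive, length >= 2.
    values : array-like
        One value per wavelength.  Molar absorptivities (M^-1 cm^-1) and
        emission intensities must be non-negative.
    kind : str
        One of ``"absorbance"``, ``"molar_absorptivity"``, ``"emission"``.
    label : str
        Free-text description.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KIND_TO_UNIT:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must all be positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.kind in ("molar_absorptivity", "emission") and np.any(vals < 0):
            raise ValueError(f"{self.kind} values must be non-negative")

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def __call__(self, query_wavelengths) -> np.ndarray:
        return interpolate(self, query_wavelengths)


def interpolate(spectrum: Spectrum, query_wavelengths) -> np.ndarray:
    """Linearly interpolate a spectrum at the requested wavelengths.

    Exact at grid nodes.  Raises :class:`WavelengthRangeError` for queries
    outside the spectrum's grid, naming the offending wavelength.
    """
    q = np.atleast_1d(np.asarray(query_wavelengths, dtype=float))
    below = q < spectrum.wl_min
    above = q > spectrum.wl_max
    if np.any(below | above):
        bad = float(q[below | above][0])
        raise WavelengthRangeError(
            f"query wavelength {bad:g} nm outside spectrum range "
            f"[{spectrum.wl_min:g}, {spectrum.wl_max:g}] nm"
        )
    out = np.interp(q, spectrum.wavelengths, spectrum.values)
    if np.isscalar(query_wavelengths) or np.ndim(query_wavelengths) == 0:
        return float(out[0])
    return out


@dataclass(frozen=True)
class SpectralTimeSeries:
    """Absorbance spectra on a shared wavelength grid, one per time point.

    ``times`` are seconds since the first LED-on and must be strictly
    increasing with ``times[0] >= 0``.  ``absorbance`` has shape
    ``(len(times), len(wavelengths))``.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        if a.shape != (t.size, wl.size):
            raise ValueError(
                f"absorbance shape {a.shape} does not match "
                f"(n_times={t.size}, n_wavelengths={wl.size})"
            )
        if np.any(wl <= 0) or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be positive and strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def spectrum_at(self, index: int) -> Spectrum:
        """The absorbance spectrum recorded at ``times[index]``."""
        return Spectrum(
            self.wavelengths,
            self.absorbance[index],
            kind="absorbance",
            label=f"{self.label} t={self.times[index]:g}s".strip(),
        )

    def at_wavelength(self, wavelength_nm: float) -> np.ndarray:
        """Absorbance-vs-time trace at one wavelength (linear interpolation)."""
        if not (self.wavelengths[0] <= wavelength_nm <= self.wavelengths[-1]):
            raise WavelengthRangeError(
                f"wavelength {wavelength_nm:g} nm outside grid "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        return np.array(
            [np.interp(wavelength_nm, self.wavelengths, row) for row in self.absorbance]
        )


def _resolve_fit_grid(
    observed: Spectrum, pure_A: Spectrum, pure_B: Spectrum, fit_range
) -> np.ndarray:
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if lo >= hi:
        raise ValueError("fit_range must be (low, high) with low < high")
    lo = max(lo, observed.wl_min, pure_A.wl_min, pure_B.wl_min)
    hi = min(hi, observed.wl_max, pure_A.wl_max, pure_B.wl_max)
    if lo >= hi:
        raise ValueError("fit_range does not overlap all three spectra")
    grid = observed.wavelengths[(observed.wavelengths >= lo) & (observed.wavelengths <= hi)]
    if grid.size < 2:
        raise ValueError("fewer than 2 observed points in fit_range")
    return grid


def decompose_mixture(
    observed: Spectrum,
    pure_A: Spectrum,
    pure_B: Spectrum,
    fit_range,
) -> tuple[float, float]:
    """Mole fraction of component A in a two-component absorbance mixture.

    Solves ``obs = c*A + (1-c)*B`` for ``c`` over ``fit_range`` (nm interval)
    by closed-form least squares on the observed spectrum's grid points inside
    the range, and clips the result to [0, 1].

    Returns
    -------
    (c, residual_norm)
        ``c`` is the mole fraction of A; ``residual_norm`` is the Euclidean
        norm of the least-squares residual at the clipped solution.

    Raises
    ------
    DegenerateSpectraError
        If the two pure spectra are indistinguishable over ``fit_range``.
    """
    grid = _resolve_fit_grid(observed, pure_A, pure_B, fit_range)
    obs = interpolate(observed, grid)
    a = interpolate(pure_A, grid)
    b = interpolate(pure_B, grid)
    d = a - b
    scale = np.linalg.norm(a) + np.linalg.norm(b)
    denom = float(d @ d)
    if denom <= (1e-12 * max(scale, 1.0)) ** 2 * grid.size:
        raise DegenerateSpectraError(
            "pure spectra are indistinguishable over the fit range; "
            "the mixture fraction is not identifiable"
        )
    c = float(d @ (obs - b)) / denom
    c = min(1.0, max(0.0, c))
    residual = obs - (c * a + (1.0 - c) * b)
    return c, float(np.linalg.norm(residual))


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Dialect: an initial header line `# units: nm, <absorbance|M-1cm-1|counts>`,
# a column-name line, then comma- or tab-separated numeric rows (delimiter
# auto-detected).  Wide time series: first column `wavelength_nm`, one column
# per timestamp named t<seconds>.
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _parse_units_header(line: str, path: str) -> str:
    stripped = line.strip()
    if not stripped.startswith("#") or "units:" not in stripped:
        raise SpectrumFormatError(
            f"{path}: missing units header; expected first line like "
            "'# units: nm, absorbance'"
        )
    decl = stripped.split("units:", 1)[1]
    parts = [p.strip() for p in decl.replace("\t", ",").split(",") if p.strip()]
    if len(parts) < 2 or parts[0] != "nm":
        raise SpectrumFormatError(
            f"{path}: malformed units header {stripped!r}; expected "
            "'# units: nm, <absorbance|M-1cm-1|counts>'"
        )
    unit = parts[1]
    if unit not in _UNIT_TO_KIND:
        raise SpectrumFormatError(
            f"{path}: unknown value unit {unit!r}; expected one of "
            f"{sorted(_UNIT_TO_KIND)}"
        )
    return _UNIT_TO_KIND[unit]


def _parse_cell(cell: str, path: str, row: int, col: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise SpectrumFormatError(
            f"{path}: non-numeric cell {cell!r} at row {row}, column {col}"
        ) from None


def _read_table(path: str) -> tuple[str, list[str], np.ndarray]:
    """Read the dialect: returns (kind, column names, data matrix)."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise SpectrumFormatError(f"{path}: too short; need header, columns and data")
    kind = _parse_units_header(lines[0], path)
    delim = _sniff_delimiter(lines[1])
    columns = [c.strip() for c in next(csv.reader([lines[1]], delimiter=delim))]
    rows = []
    for i, ln in enumerate(lines[2:], start=3):
        cells = next(csv.reader([ln], delimiter=delim))
        if len(cells) != len(columns):
            raise SpectrumFormatError(
                f"{path}: row {i} has {len(cells)} cells, expected {len(columns)}"
            )
        rows.append([_parse_cell(c, path, i, j + 1) for j, c in enumerate(cells)])
    data = np.asarray(rows, dtype=float)
    wl = data[:, 0]
    if np.unique(wl).size != wl.size:
        raise SpectrumFormatError(f"{path}: duplicate wavelengths in first column")
    if np.any(np.diff(wl) <= 0):
        raise SpectrumFormatError(
            f"{path}: wavelengths are not strictly increasing (monotonicity error)"
        )
    return kind, columns, data


def read_spectrum(path: str) -> Spectrum:
    """Read a single spectrum from a two-column delimited-text file."""
    kind, columns, data = _read_table(path)
    if data.shape[1] != 2:
        raise SpectrumFormatError(
            f"{path}: expected 2 columns for a single spectrum, got {data.shape[1]}"
        )
    label = columns[1]
    return Spectrum(data[:, 0], data[:, 1], kind=kind, label=label)


def write_spectrum(spectrum: Spectrum, path: str, delimiter: str = ",") -> None:
    unit = _KIND_TO_UNIT[spectrum.kind]
    with open(path, "w", newline="") as fh:
        fh.write(f"# units: nm, {unit}\n")
        fh.write(f"wavelength_nm{delimiter}{spectrum.label or 'value'}\n")
        for wl, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{wl:.10g}{delimiter}{v:.10g}\n")


def _time_from_column(name: str, path: str) -> float:
    if not name.startswith("t"):
        raise SpectrumFormatError(
            f"{path}: time-series column {name!r} must be named t<seconds>"
        )
    try:
        return float(name[1:])
    except ValueError:
        raise SpectrumFormatError(
            f"{path}: cannot parse time from column name {name!r}"
        ) from None


def read_time_series(path: str) -> SpectralTimeSeries:
    """Read a spectral time series.

    ``path`` is either a wide delimited-text file (first column
    ``wavelength_nm``, one column ``t<seconds>`` per spectrum) or a directory
    containing per-timestamp spectrum files plus ``manifest.csv`` with
    columns ``filename,time_s``.
    """
    if os.path.isdir(path):
        return _read_time_series_dir(path)
    kind, columns, data = _read_table(path)
    if kind != "absorbance":
        raise SpectrumFormatError(f"{path}: time series must carry absorbance units")
    if data.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: no time columns found")
    times = np.array([_time_from_column(c, path) for c in columns[1:]])
    order = np.argsort(times)
    return SpectralTimeSeries(
        times=times[order],
        wavelengths=data[:, 0],
        absorbance=data[:, 1:][:, order].T,
        label=os.path.basename(path),
    )


def _read_time_series_dir(path: str) -> SpectralTimeSeries:
    manifest = os.path.join(path, "manifest.csv")
    if not os.path.exists(manifest):
        raise SpectrumFormatError(f"{path}: directory time series needs manifest.csv")
    entries: list[tuple[float, str]] = []
    with open(manifest, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["filename", "time_s"]:
            raise SpectrumFormatError(
                f"{manifest}: manifest must have columns filename,time_s"
            )
        for i, row in enumerate(reader, start=2):
            entries.append((_parse_cell(row[1], manifest, i, 2), row[0].strip()))
    entries.sort()
    spectra = [read_spectrum(os.path.join(path, fname)) for _, fname in entries]
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != grid.shape or not np.allclose(s.wavelengths, grid):
            raise SpectrumFormatError(
                f"{path}: spectra in a time-series directory must share one grid"
            )
    return SpectralTimeSeries(
        times=np.array([t for t, _ in entries]),
        wavelengths=grid,
        absorbance=np.vstack([s.values for s in spectra]),
        label=os.path.basename(path.rstrip("/")),
    )


def write_time_series(ts: SpectralTimeSeries, path: str, delimiter: str = ",") -> None:
    """Write a time series in the wide dialect (round-trippable)."""
    with open(path, "w", newline="") as fh:
        fh.write("# units: nm, absorbance\n")
        cols = ["wavelength_nm"] + [f"t{t:g}" for t in ts.times]
        fh.write(delimiter.join(cols) + "\n")
        for j, wl in enumerate(ts.wavelengths):
            row = [f"{wl:.10g}"] + [f"{ts.absorbance[i, j]:.10g}" for i in range(len(ts))]
            fh.write(delimiter.join(row) + "\n")
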