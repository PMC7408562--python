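"""Wavelength-indexed spectra: container, text I/O, and spectral transforms.

All spectra in the package live on a strictly ascending wavelength grid in
nanometres.  Values are absorbance (AU), fluorescence emission intensity
(AU), or molar extinction (M^-1 cm^-1), declared through ``kind``.

The transforms provided here are the ones the downstream analyses need:

* inner-filter correction of fluorescence intensities for the attenuation
  of excitation and emission light by an absorbing ligand,
* trapezoidal band integration with interpolated endpoints,
* a quadratic local-polynomial (Savitzky-Golay-type) second derivative,
* linear resampling onto a caller-supplied grid (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, RangeError

SpectrumKind = Literal["absorbance", "emission", "extinction"]

_VALID_KINDS = ("absorbance", "emission", "extinction")


@dataclass(frozen=True)
class Spectrum:
    """A signal sampled on a strictly ascending wavelength grid (nm).

    Parameters
    ----------
    wavelengths:
        Wavelengths in nm, strictly increasing, length >= 2.
    values:
        Per-wavelength signal, same length as ``wavelengths``.
    kind:
        One of ``"absorbance"``, ``"emission"``, ``"extinction"``.
        Extinction values must be non-negative.
    label:
        Free-text description carried through I/O.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "emission"
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise InvalidInputError("wavelengths and values must be 1-D")
        if wl.size < 2:
            raise InvalidInputError("a spectrum needs at least 2 points")
        if wl.size != vals.size:
            raise InvalidInputError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise InvalidInputError("non-finite entries in spectrum")
        diffs = np.diff(wl)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise InvalidInputError(
                f"wavelengths must be strictly increasing (violation at row {row})"
            )
        if self.kind not in _VALID_KINDS:
            raise InvalidParameterError(
                f"kind must be one of {_VALID_KINDS}, got {self.kind!r}"
            )
        if self.kind == "extinction" and np.any(vals < 0):
            raise InvalidInputError("extinction values must be >= 0")

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class InnerFilterInput:
    """Measured intensity plus the absorbance differences that attenuate it.

    ``Aex`` and ``Aem`` are the absorbance *changes* caused by ligand
    addition at the excitation wavelength and at the emission
    wavelength(s), respectively.  ``Aem`` may be a scalar or an array
    matching the shape of ``Iobs``.
    """

    Iobs: float | np.ndarray
    Aex: float
    Aem: float | np.ndarray

    def __post_init__(self) -> None:
        iobs = np.asarray(self.Iobs, dtype=float)
        aem = np.asarray(self.Aem, dtype=float)
        if not np.isfinite(self.Aex) or not np.all(np.isfinite(aem)):
            raise InvalidInputError("absorbances must be finite")
        if not np.all(np.isfinite(iobs)):
            raise InvalidInputError("Iobs must be finite")
        if np.any(iobs < 0):
            raise InvalidInputError("Iobs must be >= 0")


def inner_filter_correct(x: InnerFilterInput) -> float | np.ndarray:
    """Correct a fluorescence intensity for primary/secondary inner-filter
    attenuation: ``I_cor = I_obs * 10**((A_ex + A_em) / 2)``.

    The half-power form assumes the average light path through a centred
    1 cm cuvette.  Works element-wise when ``Aem`` varies with wavelength.
    """
    iobs = np.asarray(x.Iobs, dtype=float)
    corrected = iobs * 10.0 ** ((x.Aex + np.asarray(x.Aem, dtype=float)) / 2.0)
    if np.isscalar(x.Iobs) or (isinstance(x.Iobs, float)):
        return float(corrected)
    return corrected


def inner_filter_correct_spectrum(
    s: Spectrum, Aex: float, Aem: float | np.ndarray
) -> Spectrum:
    """Apply the inner-filter correction to an emission spectrum."""
    corrected = inner_filter_correct(InnerFilterInput(s.values, Aex, Aem))
    return s.with_values(np.asarray(corrected))


def band_area(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over ``[lo, hi]`` (value*nm).

    Endpoints falling between grid points are included by linear
    interpolation, so the area is additive over contiguous subintervals.
    """
    if not (lo < hi):
        raise RangeError(f"need lo < hi, got [{lo}, {hi}]")
    wl_lo, wl_hi = s.range
    a, b = max(lo, wl_lo), min(hi, wl_hi)
    if a >= b:
        raise RangeError(
            f"integration window [{lo}, {hi}] does not overlap "
            f"spectrum range [{wl_lo}, {wl_hi}]"
        )
    wl = s.wavelengths
    inside = (wl > a) & (wl < b)
    grid = np.concatenate(([a], wl[inside], [b]))
    vals = np.interp(grid, wl, s.values)
    return float(np.trapezoid(vals, grid))


def second_derivative(s: Spectrum, window: int = 7) -> Spectrum:
    """Smoothing second derivative d2(value)/d(wavelength)2.

    At each point a quadratic is fitted by least squares to the ``window``
    nearest grid points (centred in the interior, one-sided at the edges)
    and its curvature ``2*c2`` is taken as the derivative.  Exact for
    polynomials of degree <= 2; works on non-uniform grids.
    """
    n = s.wavelengths.size
    if window % 2 == 0:
        raise InvalidParameterError(f"window must be odd, got {window}")
    if window < 5:
        raise InvalidParameterError(f"window must be >= 5, got {window}")
    if window > n:
        raise InvalidParameterError(
            f"window {window} exceeds series length {n}"
        )
    half = window // 2
    wl, vals = s.wavelengths, s.values
    out = np.empty(n)
    for i in range(n):
        start = min(max(i - half, 0), n - window)
        sl = slice(start, start + window)
        x = wl[sl] - wl[i]
        coeffs = np.polynomial.polynomial.polyfit(x, vals[sl], 2)
        out[i] = 2.0 * coeffs[2]
    return Spectrum(wl.copy(), out, kind=s.kind, label=f"d2({s.label})")


def resample(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linear interpolation of the spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                      dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise InvalidInputError("grid must be a non-empty 1-D array")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be strictly ascending")
    lo, hi = s.range
    if grid[0] < lo or grid[-1] > hi:
        raise RangeError(
            f"requested grid [{grid[0]}, {grid[-1]}] extends outside the "
            f"measured range [{lo}, {hi}]; extrapolation is not supported"
        )
    vals = np.interp(grid, s.wavelengths, s.values)
    return Spectrum(grid, vals, kind=s.kind, label=s.label)


# ----------------------------------------------------------------------
# Delimited-text I/O.  Format: optional `# key: value` comment lines, a
# header `wavelength_nm,<value_name>`, then two numeric columns.  Comma or
# tab delimited.  Values are written with 10 significant digits so a
# read -> write -> read round trip is decimal-identical.
# ----------------------------------------------------------------------

_KIND_BY_NAME = {
    "absorbance": "absorbance",
    "intensity": "emission",
    "emission": "emission",
    "extinction": "extinction",
    "epsilon": "extinction",
}


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_spectrum(path: str | Path, kind: SpectrumKind | None = None) -> Spectrum:
    """Read a two-column delimited spectrum file.

    The header names the value column; when ``kind`` is not given it is
    inferred from that name (``absorbance``/``intensity``/``extinction``).
    Non-monotonic wavelength columns are rejected with the offending row
    number in the message.
    """
    path = Path(path)
    label = path.stem
    header = None
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line and line.lower().startswith("# label"):
                    label = line.split(":", 1)[1].strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(_sniff_delimiter(line))]
                if len(header) != 2 or header[0] != "wavelength_nm":
                    raise InvalidInputError(
                        f"{path}: expected header 'wavelength_nm,<value_name>', "
                        f"got {line!r}"
                    )
                continue
            parts = line.split(_sniff_delimiter(line))
            if len(parts) != 2:
                raise InvalidInputError(f"{path}:{lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1]), lineno))
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from exc
    if header is None or len(rows) < 2:
        raise InvalidInputError(f"{path}: no data rows found")
    wl = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    bad = np.nonzero(np.diff(wl) <= 0)[0]
    if bad.size:
        raise InvalidInputError(
            f"{path}: wavelength column not strictly increasing at row "
            f"{rows[int(bad[0]) + 1][2]}"
        )
    if kind is None:
        kind = _KIND_BY_NAME.get(header[1].split("_")[0].lower(), "emission")
    return Spectrum(wl, vals, kind=kind, label=label)


_VALUE_NAME = {
    "absorbance": "absorbance_AU",
    "emission": "intensity_AU",
    "extinction": "extinction_M-1cm-1",
}


def write_spectrum(s: Spectrum, path: str | Path,
                   metadata: dict[str, object] | None = None) -> None:
    """Write a spectrum as comma-delimited text with 10 significant digits."""
    path = Path(path)
    lines = []
    if s.label:
        lines.append(f"# label: {s.label}")
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append(f"wavelength_nm,{_VALUE_NAME[s.kind]}")
    for w, v in zip(s.wavelengths, s.values):
        lines.append(f"{w:.10g},{v:.10g}")
    path.write_text("\n".join(lines) + "\n")
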