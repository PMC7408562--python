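"""Steady-state fluorescence anisotropy and lipid phase-transition fitting.

The anisotropy of a membrane probe such as DPH reports the rotational
freedom of the acyl-chain region: high (~0.3-0.4) in the ordered gel
phase, low (~0.1) in the fluid phase, with a sharp sigmoidal drop at
the lipid melting temperature.  From polarized intensity components,

    r = (I_VV - G I_VH) / (I_VV + 2 G I_VH),   G = I_HV / I_HH,

where G corrects the detection chain's transmissivity bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    ModelMismatchError,
)


@dataclass(frozen=True)
class PolarizedReading:
    """One set of polarized intensity components at a temperature (°C).

    I_HV and I_HH may be omitted (None) when the instrument pre-corrects
    for transmissivity; G then defaults to 1.
    """

    I_VV: float
    I_VH: float
    temperature: float  # °C
    I_HV: float | None = None
    I_HH: float | None = None

    def __post_init__(self) -> None:
        for name in ("I_VV", "I_VH"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.I_VV + self.I_VH <= 0:
            raise InvalidInputError("I_VV + I_VH must be > 0")


@dataclass(frozen=True)
class TransitionFit:
    """Logistic fit of anisotropy vs. temperature across a phase transition."""

    T_m: float       # melting temperature, °C
    r_low_T: float   # gel-phase plateau (ordered, high r)
    r_high_T: float  # fluid-phase plateau (disordered, low r)
    width: float     # transition width, °C
    residual_sd: float


def g_factor(I_HV: float, I_HH: float) -> float:
    """Instrumental polarization correction G = I_HV / I_HH."""
    if I_HH <= 0:
        raise InvalidInputError("I_HH must be > 0")
    return I_HV / I_HH


def steady_state_anisotropy(reading: PolarizedReading,
                            G: float | None = None) -> float:
    """r = (I_VV - G I_VH) / (I_VV + 2 G I_VH).

    G is computed from the reading's horizontal-excitation components
    when present, taken as 1 otherwise, unless supplied explicitly.
    """
    if G is None:
        if reading.I_HV is not None and reading.I_HH is not None:
            G = g_factor(reading.I_HV, reading.I_HH)
        else:
            G = 1.0
    denom = reading.I_VV + 2.0 * G * reading.I_VH
    if denom <= 0:
        raise InvalidInputError("anisotropy denominator must be > 0")
    return (reading.I_VV - G * reading.I_VH) / denom


def intensities_from_anisotropy(r: float, G: float = 1.0,
                                I_VH: float = 1.0) -> tuple[float, float]:
    """Invert the anisotropy formula: (I_VV, I_VH) reproducing ``r`` at G.

    Only r in (-0.5, 1) is attainable with non-negative intensities.
    """
    if not (-0.5 < r < 1.0):
        raise InvalidInputError(f"anisotropy {r} not attainable")
    I_VV = G * I_VH * (1.0 + 2.0 * r) / (1.0 - r)
    return I_VV, I_VH


def _logistic(T, T_m, width, r_low, r_high):
    return r_high + (r_low - r_high) / (1.0 + np.exp((T - T_m) / width))


def fit_thermotropic_transition(
    curve: Sequence[tuple[float, float]],
    amplitude_sd_factor: float = 3.0,
) -> TransitionFit:
    """Fit r(T) = r_high + (r_low - r_high)/(1 + exp((T - T_m)/width)).

    ``curve`` is a sequence of (temperature °C, anisotropy) pairs spanning
    both plateaus.  Raises ``ModelMismatchError`` when the fitted
    amplitude is indistinguishable from noise (< ``amplitude_sd_factor``
    residual SDs).
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 8:
        raise InsufficientDataError(
            "transition fit needs >= 8 (temperature, r) points"
        )
    T, r = arr[:, 0], arr[:, 1]
    order = np.argsort(T)
    T, r = T[order], r[order]
    span = T[-1] - T[0]
    r_lo0, r_hi0 = float(r[:2].mean()), float(r[-2:].mean())
    # T_m guess: steepest local change
    tm0 = float(T[np.argmax(np.abs(np.diff(r)))])
    p0 = [tm0, max(span / 20.0, 0.2), r_lo0, r_hi0]
    try:
        popt, _ = optimize.curve_fit(
            _logistic, T, r, p0=p0,
            bounds=([T[0] - span, 1e-3, -0.5, -0.5],
                    [T[-1] + span, span, 1.0, 1.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"transition fit failed: {exc}") from exc
    tm, width, r_low, r_high = (float(v) for v in popt)
    resid = r - _logistic(T, *popt)
    sd = float(np.std(resid, ddof=min(4, r.size - 1)))
    if abs(r_low - r_high) <= amplitude_sd_factor * sd + 1e-9:
        raise ModelMismatchError(
            "no detectable transition: amplitude "
            f"{abs(r_low - r_high):.3g} < {amplitude_sd_factor} x residual SD "
            f"{sd:.3g}"
        )
    return TransitionFit(T_m=tm, r_low_T=r_low, r_high_T=r_high,
                         width=width, residual_sd=sd)
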