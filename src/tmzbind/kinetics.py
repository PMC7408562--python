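"""First-order degradation kinetics from absorbance time courses.

Temozolomide opens its tetrazinone ring at physiological pH, decaying
into MTIC and then AIC; the loss is tracked as the 329 nm absorbance
band shrinking over time.  The observable envelope is modelled as a
single exponential

    A(t) = A_inf + (A0 - A_inf) exp(-k t),      t_1/2 = ln 2 / k,

with time in hours.  ``compare_decay`` orders several conditions (e.g.
increasing protein concentration) by their fitted rate constants to
quantify binding-induced stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
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
class DecaySeries:
    """Time (hours, ascending from 0) vs. signal (AU, > 0)."""

    time: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.size != s.size:
            raise InvalidInputError("time/signal length mismatch")
        if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must ascend strictly from 0")
        if np.any(s <= 0):
            raise InvalidInputError("signal must be > 0")


@dataclass(frozen=True)
class DecayFit:
    k: float       # h^-1
    k_se: float
    A0: float      # AU
    A_inf: float   # AU

    @property
    def t_half(self) -> float:
        """Half-life ln(2)/k in hours."""
        return np.log(2.0) / self.k


def normalize_decay(s: DecaySeries) -> DecaySeries:
    """Divide the series by its t = 0 value; first point becomes exactly 1."""
    s0 = s.signal[0]
    if s0 <= 0:
        raise InvalidInputError("initial signal must be > 0")
    return replace(s, signal=s.signal / s0)


def _decay(t, k, A0, A_inf):
    return A_inf + (A0 - A_inf) * np.exp(-k * t)


def fit_first_order_decay(s: DecaySeries,
                          fit_plateau: bool = False) -> DecayFit:
    """Least-squares fit of A(t) = A_inf + (A0 - A_inf) e^(-kt).

    ``fit_plateau`` frees A_inf; otherwise decay is assumed complete
    (A_inf = 0).  Signals drifting upward beyond noise raise
    ``ModelMismatchError``.
    """
    t, sig = s.time, s.signal
    if t.size < 4:
        raise InsufficientDataError("decay fit needs >= 4 time points")
    rise = np.diff(sig)
    noise = max(float(np.std(rise)), 1e-12)
    if sig[-1] > sig[0] + 3 * noise or np.all(rise > 0):
        raise ModelMismatchError("signal increases with time; not a decay")

    a0 = float(sig[0])
    # crude rate guess from the time the signal falls to ~60% of its drop
    drop = sig - sig.min()
    target = drop[0] * np.exp(-1.0)
    below = np.nonzero(drop <= target)[0]
    tchar = float(t[below[0]]) if below.size and t[below[0]] > 0 else float(
        t[-1] / 2.0)
    k0 = 1.0 / max(tchar, 1e-6)
    try:
        if fit_plateau:
            popt, pcov = optimize.curve_fit(
                _decay, t, sig, p0=[k0, a0, float(sig.min())],
                bounds=([1e-12, 0, 0], [np.inf, np.inf, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
            )
            k, A0, A_inf = (float(v) for v in popt)
            k_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
        else:
            popt, pcov = optimize.curve_fit(
                lambda x, k, A0: _decay(x, k, A0, 0.0), t, sig,
                p0=[k0, a0], bounds=([1e-12, 0], [np.inf, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
            )
            k, A0 = (float(v) for v in popt)
            A_inf = 0.0
            k_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"decay fit failed: {exc}") from exc
    return DecayFit(k=k, k_se=k_se, A0=A0, A_inf=A_inf)


@dataclass(frozen=True)
class DecayComparison:
    fits: tuple[DecayFit, ...]
    labels: tuple[str, ...]
    strictly_decreasing: bool

    @property
    def rate_constants(self) -> tuple[float, ...]:
        return tuple(f.k for f in self.fits)


def compare_decay(series_list: Sequence[DecaySeries],
                  fit_plateau: bool = False) -> DecayComparison:
    """Fit each series and report whether the rate constants decrease
    strictly along the supplied order (e.g. with rising protein
    concentration, binding slows hydrolysis)."""
    if len(series_list) < 2:
        raise InsufficientDataError("comparison needs >= 2 series")
    fits = tuple(fit_first_order_decay(s, fit_plateau=fit_plateau)
                 for s in series_list)
    ks = [f.k for f in fits]
    decreasing = all(b < a for a, b in zip(ks, ks[1:]))
    return DecayComparison(
        fits=fits,
        labels=tuple(s.label for s in series_list),
        strictly_decreasing=decreasing,
    )
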