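"""Fluorescence-quenching analysis of 1:1 drug-protein association.

Implements the standard ladder of analyses applied to a quenching
titration of a tryptophan-bearing protein by an absorbing ligand:

* Stern-Volmer regression  I0/I = 1 + K_SV [Q],
* the apparent bimolecular quenching rate k_q = K_SV / tau0 and its
  comparison against the diffusion-collision ceiling (static vs.
  dynamic quenching),
* the 1:1 binding isotherm
  dI = (I0 - Ic) [Q] / (1/K_a + [Q]),
  valid when ligand is in large excess over protein (no depletion),
* K_d = 1/K_a, dG = -RT ln K_a, and van't Hoff estimation of dH and dS
  from the temperature dependence of K_a.

Intensities are integrated band areas after inner-filter correction;
concentrations are molar; temperatures are Kelvin internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.3145

#: Diffusion-collision ceiling for quencher-macromolecule encounters,
#: M^-1 s^-1.  An apparent k_q above this cannot be purely collisional.
DIFFUSION_LIMIT = 2.0e10


@dataclass(frozen=True)
class QuenchTitration:
    """Quencher concentration (M) vs. integrated emission intensity (AU).

    The first point is expected at zero quencher and defines I0 unless
    ``I0`` is supplied explicitly.
    """

    quencher_conc: np.ndarray
    intensity: np.ndarray
    temperature: float = 298.15  # K
    I0: float | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_conc, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "quencher_conc", q)
        object.__setattr__(self, "intensity", i)
        if q.size != i.size:
            raise InvalidInputError("concentration/intensity length mismatch")
        if np.any(q < 0):
            raise InvalidInputError("quencher concentrations must be >= 0")
        if np.any(i <= 0):
            raise InvalidInputError("intensities must be > 0")
        if self.I0 is None and q[0] != 0.0:
            raise InvalidInputError(
                "first point must be at zero quencher unless I0 is supplied"
            )

    @property
    def reference_intensity(self) -> float:
        return float(self.I0) if self.I0 is not None else float(self.intensity[0])


@dataclass(frozen=True)
class SternVolmerFit:
    K_SV: float           # M^-1
    K_SV_se: float        # M^-1
    intercept: float      # dimensionless, ~1 for well-behaved data
    r_squared: float
    non_quenching: bool = False  # set when the fitted slope is negative


@dataclass(frozen=True)
class BindingFit:
    K_a: float    # M^-1
    K_a_se: float
    I0: float     # AU
    Ic: float     # AU, fluorescence of the fully complexed protein
    Ic_se: float

    @property
    def K_d(self) -> float:
        """Dissociation constant, M."""
        return 1.0 / self.K_a


@dataclass(frozen=True)
class ThermoParams:
    """Binding thermodynamics at temperature ``T`` (K), J-based units."""

    dG: float          # J mol^-1
    dH: float          # J mol^-1
    dS: float          # J mol^-1 K^-1
    T: float           # K
    R_gas: float = R_GAS

    def __post_init__(self) -> None:
        # dG = dH - T dS must hold by construction
        resid = abs(self.dG - (self.dH - self.T * self.dS))
        scale = max(abs(self.dG), abs(self.dH), abs(self.T * self.dS), 1.0)
        if resid / scale > 1e-6:
            raise InvalidInputError("inconsistent dG, dH, dS at T")


def fit_stern_volmer(t: QuenchTitration) -> SternVolmerFit:
    """Ordinary least-squares fit of I0/I vs. [Q]; the slope is K_SV."""
    q = t.quencher_conc
    if np.unique(q).size < 3:
        raise InsufficientDataError(
            "Stern-Volmer regression needs >= 3 distinct concentrations"
        )
    ratio = t.reference_intensity / t.intensity
    res = stats.linregress(q, ratio)
    return SternVolmerFit(
        K_SV=float(res.slope),
        K_SV_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        non_quenching=bool(res.slope < 0),
    )


def bimolecular_rate_constant(K_SV: float, tau0: float) -> float:
    """Apparent bimolecular quenching rate k_q = K_SV / tau0 (M^-1 s^-1).

    ``tau0`` is the unquenched fluorophore lifetime in seconds (6.4 ns is
    the standard value for protein tryptophan).
    """
    if tau0 <= 0:
        raise InvalidParameterError(f"tau0 must be > 0, got {tau0}")
    return K_SV / tau0


def classify_quenching(k_q: float,
                       diffusion_limit: float = DIFFUSION_LIMIT) -> str:
    """Classify the quenching mechanism from the apparent rate constant.

    Returns ``"static"`` when ``k_q`` strictly exceeds the diffusion
    ceiling (ground-state complex formation), else
    ``"dynamic-compatible"``.
    """
    if k_q < 0:
        raise InvalidParameterError("k_q must be >= 0")
    return "static" if k_q > diffusion_limit else "dynamic-compatible"


def _isotherm(q, K_a, Ic, I0):
    return (I0 - Ic) * q / (1.0 / K_a + q)


def fit_binding_isotherm(t: QuenchTitration, I0: float | None = None,
                         max_restarts: int = 5) -> BindingFit:
    """Fit the 1:1 isotherm dI = (I0 - Ic) [Q] / (1/K_a + [Q]).

    I0 is taken from the zero-quencher point unless supplied.  Initial
    guesses come from a double-reciprocal linearization of the isotherm;
    Ic is bounded to [0, I0].  Assumes ligand excess (no depletion).
    """
    q = t.quencher_conc
    uq = np.unique(q[q > 0])
    if uq.size < 3 or np.unique(q).size < 4:
        raise InsufficientDataError("isotherm fit needs >= 4 distinct concentrations")
    if uq[-1] / uq[0] < 5:
        raise InsufficientDataError(
            "quencher concentrations must span at least a factor of 5"
        )
    i0 = float(I0) if I0 is not None else t.reference_intensity
    mask = q > 0
    qq, di = q[mask], i0 - t.intensity[mask]

    # double-reciprocal linearization: 1/dI = 1/(I0-Ic) + 1/(Ka (I0-Ic)) * 1/[Q]
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = di > 0
        if ok.sum() >= 2:
            lin = stats.linregress(1.0 / qq[ok], 1.0 / di[ok])
            amp0 = 1.0 / lin.intercept if lin.intercept > 0 else float(di.max())
            ka0 = lin.intercept / lin.slope if lin.slope > 0 else 1.0 / np.median(qq)
        else:
            amp0, ka0 = float(max(di.max(), i0 * 0.1)), 1.0 / np.median(qq)
    ka0 = abs(ka0) if ka0 != 0 else 1.0 / np.median(qq)
    ic0 = float(np.clip(i0 - amp0, 0.0, i0))

    rng = np.random.default_rng(0)
    best = None
    best_cost = np.inf
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = [ka0, ic0]
        else:
            p0 = [ka0 * rng.uniform(0.3, 3.0),
                  float(np.clip(ic0 + rng.normal(0, 0.1 * i0), 0, i0))]
        try:
            popt, pcov = optimize.curve_fit(
                lambda x, ka, ic: _isotherm(x, ka, ic, i0),
                qq, di, p0=p0,
                bounds=([1e-12, 0.0], [np.inf, i0]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((di - _isotherm(qq, *popt, i0)) ** 2))
        if cost < best_cost:
            best, best_cost = (popt, pcov), cost
    if best is None:
        raise FitFailureError("isotherm fit did not converge", best_residual=None)
    (ka, ic), pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return BindingFit(K_a=float(ka), K_a_se=float(se[0]), I0=i0,
                      Ic=float(ic), Ic_se=float(se[1]))


def dissociation_constant(K_a: float) -> float:
    """K_d = 1/K_a (M)."""
    if K_a <= 0:
        raise InvalidParameterError(f"K_a must be > 0, got {K_a}")
    return 1.0 / K_a


def gibbs_free_energy(K_a: float, T: float = 298.15) -> float:
    """Standard binding free energy dG = -R T ln K_a (J mol^-1)."""
    if K_a <= 0 or T <= 0:
        raise InvalidParameterError("need K_a > 0 and T > 0")
    return -R_GAS * T * np.log(K_a)


def vant_hoff_two_point(K_a1: float, T1: float,
                        K_a2: float, T2: float) -> ThermoParams:
    """Closed-form van't Hoff estimate from association constants at two
    temperatures (K).

    dH = -R ln(K2/K1) / (1/T2 - 1/T1); dS from dG(T2) = dH - T2 dS.
    """
    if T1 == T2:
        raise InvalidParameterError("temperatures must differ")
    if K_a1 <= 0 or K_a2 <= 0:
        raise InvalidParameterError("association constants must be > 0")
    if K_a1 == K_a2:
        dH = 0.0
    else:
        dH = -R_GAS * np.log(K_a2 / K_a1) / (1.0 / T2 - 1.0 / T1)
    dG = gibbs_free_energy(K_a2, T2)
    dS = (dH - dG) / T2
    return ThermoParams(dG=float(dG), dH=float(dH), dS=float(dS), T=float(T2))


def vant_hoff_regression(K_a: np.ndarray, T: np.ndarray) -> ThermoParams:
    """van't Hoff line ln K_a = -dH/(R T) + dS/R fitted over >= 3
    temperatures; dG reported at the highest temperature supplied."""
    K_a = np.asarray(K_a, dtype=float)
    T = np.asarray(T, dtype=float)
    if K_a.size != T.size or K_a.size < 3:
        raise InsufficientDataError("need >= 3 (K_a, T) pairs")
    if np.any(K_a <= 0) or np.any(T <= 0):
        raise InvalidParameterError("K_a and T must be > 0")
    res = stats.linregress(1.0 / T, np.log(K_a))
    dH = -R_GAS * res.slope
    Tref = float(T.max())
    dS = R_GAS * res.intercept
    dG = dH - Tref * dS
    return ThermoParams(dG=float(dG), dH=float(dH), dS=float(dS), T=Tref)
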