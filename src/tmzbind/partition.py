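"""Membrane/water partition coefficient from vesicle absorbance titrations.

Adding lipid vesicles to a drug solution shifts part of the drug into
the bilayer, whose bound-state extinction differs from the aqueous one.
The absorbance change at a fixed wavelength follows the saturation law

    dA = dA_max [lipid] / (1/(K_p γ) + [lipid])

where K_p is the dimensionless membrane/water partition coefficient and
γ (M⁻¹) the lipid molar volume.  Two fitting modes are provided:

* ``fixed_bound`` — dA_max is supplied (the bound-state absorbance is
  fixed from an independent extinction estimate) and only K_p floats;
* ``free_bound`` — both parameters float; when the data cannot pin K_p
  down (relative standard error above 50%) the result is flagged as an
  upper bound only, which is the honest outcome for weakly partitioning
  drugs on practical lipid ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

#: Default lipid molar volume, M^-1 (phosphatidylcholine bilayers).
GAMMA_DEFAULT = 0.9

PartitionMode = Literal["fixed_bound", "free_bound"]


@dataclass(frozen=True)
class PartitionTitration:
    """Total lipid concentration (M) vs. absorbance change dA >= 0 (AU).

    dA is free-state absorbance minus observed absorbance (the drug's
    extinction drops on membrane binding), measured either directly at
    the absorption peak or as a second-derivative amplitude.
    """

    lipid_conc: np.ndarray
    delta_A: np.ndarray
    molar_volume_gamma: float = GAMMA_DEFAULT

    def __post_init__(self) -> None:
        lc = np.asarray(self.lipid_conc, dtype=float)
        da = np.asarray(self.delta_A, dtype=float)
        object.__setattr__(self, "lipid_conc", lc)
        object.__setattr__(self, "delta_A", da)
        if lc.size != da.size:
            raise InvalidInputError("lipid/delta_A length mismatch")
        if np.any(lc < 0) or np.any(np.diff(lc) < 0):
            raise InvalidInputError("lipid concentrations must be >= 0 ascending")
        if self.molar_volume_gamma <= 0:
            raise InvalidParameterError("molar volume gamma must be > 0")


@dataclass(frozen=True)
class PartitionFit:
    K_p: float
    K_p_se: float
    delta_A_max: float
    delta_A_max_se: float
    mode: PartitionMode
    upper_bound_flag: bool = False  # K_p unresolved; only an upper bound holds


def partition_curve(lipid: np.ndarray, K_p: float, delta_A_max: float,
                    gamma: float = GAMMA_DEFAULT) -> np.ndarray:
    """Forward model dA([lipid])."""
    lipid = np.asarray(lipid, dtype=float)
    return delta_A_max * lipid / (1.0 / (K_p * gamma) + lipid)


def fit_partition(t: PartitionTitration, mode: PartitionMode = "fixed_bound",
                  delta_A_max: float | None = None,
                  se_flag_threshold: float = 0.5) -> PartitionFit:
    """Least-squares estimate of K_p from a lipid titration.

    In ``fixed_bound`` mode ``delta_A_max`` must be supplied and only
    K_p is fitted; in ``free_bound`` mode both float and the
    ``upper_bound_flag`` is set when rel. SE of K_p > ``se_flag_threshold``.
    """
    lc, da, gamma = t.lipid_conc, t.delta_A, t.molar_volume_gamma
    if np.unique(lc).size < 4 or lc[0] != 0.0:
        raise InsufficientDataError(
            "partition fit needs >= 4 lipid concentrations including 0"
        )
    pos = lc > 0
    # half-saturation guess from where dA crosses half its max
    damax0 = float(da.max()) if da.max() > 0 else 1.0
    half = damax0 / 2.0
    above = np.nonzero(da >= half)[0]
    lhalf = float(lc[above[0]]) if above.size and lc[above[0]] > 0 else float(
        np.median(lc[pos]))
    kp0 = max(1.0 / (gamma * lhalf), 1e-6)

    if mode == "fixed_bound":
        if delta_A_max is None:
            raise InvalidParameterError(
                "fixed_bound mode requires delta_A_max (the absorbance change "
                "at full membrane binding)"
            )
        try:
            popt, pcov = optimize.curve_fit(
                lambda x, kp: partition_curve(x, kp, delta_A_max, gamma),
                lc, da, p0=[kp0], bounds=(1e-12, np.inf),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitFailureError(f"partition fit failed: {exc}") from exc
        kp = float(popt[0])
        kp_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
        return PartitionFit(K_p=kp, K_p_se=kp_se, delta_A_max=delta_A_max,
                            delta_A_max_se=0.0, mode=mode)
    if mode != "free_bound":
        raise InvalidParameterError(f"unknown mode {mode!r}")
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, kp, dmax: partition_curve(x, kp, dmax, gamma),
            lc, da, p0=[kp0, damax0 * 1.5],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"partition fit failed: {exc}") from exc
    kp, dmax = (float(v) for v in popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return PartitionFit(
        K_p=kp, K_p_se=float(se[0]), delta_A_max=dmax,
        delta_A_max_se=float(se[1]), mode=mode,
        upper_bound_flag=bool(se[0] > se_flag_threshold * abs(kp)),
    )


def lipid_bound_fraction(K_p: float, gamma: float, lipid_conc: float) -> float:
    """Fraction of drug in the membrane phase at a given lipid concentration:
    K_p γ [lipid] / (1 + K_p γ [lipid])."""
    if K_p < 0 or gamma < 0 or lipid_conc < 0:
        raise InvalidParameterError("all arguments must be >= 0")
    x = K_p * gamma * lipid_conc
    if np.isinf(x):
        return 1.0
    return x / (1.0 + x)
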