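"""Competitive equilibrium distribution of a drug among plasma proteins.

Each protein is treated as an independent pool of identical 1:1 sites
with its own association constant.  When protein is in large excess
over drug (the default, "no depletion" mode), the bound fractions are

    f_i = K_a,i [P_i] / (1 + sum_j K_a,j [P_j]),
    f_free = 1 / (1 + sum_j K_a,j [P_j]),

which always sum to one.  An optional mass-balance mode solves the
coupled equilibria for a finite total drug concentration by bisection
on the free drug concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class ProteinSite:
    name: str
    K_a: float   # M^-1
    conc: float  # M (total protein)

    def __post_init__(self) -> None:
        if self.K_a < 0 or self.conc < 0:
            raise InvalidInputError("K_a and conc must be >= 0")


@dataclass(frozen=True)
class PlasmaComposition:
    proteins: tuple[ProteinSite, ...]
    drug_conc: float | None = None  # M, only needed for depletion mode

    def __post_init__(self) -> None:
        object.__setattr__(self, "proteins", tuple(self.proteins))
        if not self.proteins:
            raise InvalidInputError("composition must list at least one protein")
        names = [p.name for p in self.proteins]
        if len(set(names)) != len(names):
            raise InvalidInputError("protein names must be unique")


def bound_fractions(c: PlasmaComposition,
                    deplete_drug: bool = False) -> dict[str, float]:
    """Per-protein bound fractions plus the free fraction (key ``"free"``).

    With ``deplete_drug`` the finite total drug concentration
    ``c.drug_conc`` is honoured through mass balance on both drug and
    protein; otherwise protein excess is assumed.
    """
    if not deplete_drug:
        weights = {p.name: p.K_a * p.conc for p in c.proteins}
        denom = 1.0 + sum(weights.values())
        out = {name: w / denom for name, w in weights.items()}
        out["free"] = 1.0 / denom
        return out
    if c.drug_conc is None or c.drug_conc <= 0:
        raise InvalidParameterError(
            "depletion-aware mode requires a positive drug_conc"
        )
    D = c.drug_conc

    def residual(free):
        # total drug accounted for at a trial free concentration
        bound = sum(
            p.conc * p.K_a * free / (1.0 + p.K_a * free) for p in c.proteins
        )
        return free + bound - D

    free = optimize.brentq(residual, 0.0, D, xtol=1e-18, rtol=1e-15)
    out = {}
    for p in c.proteins:
        complex_conc = p.conc * p.K_a * free / (1.0 + p.K_a * free)
        out[p.name] = complex_conc / D
    out["free"] = free / D
    return out


def bound_fraction_vs_protein_conc(K_a: float,
                                   conc_grid: np.ndarray) -> np.ndarray:
    """Single-protein bound fraction K_a [P] / (1 + K_a [P]) on a
    concentration grid (monotone increasing in [P])."""
    grid = np.asarray(conc_grid, dtype=float)
    if K_a < 0 or np.any(grid < 0):
        raise InvalidParameterError("K_a and concentrations must be >= 0")
    x = K_a * grid
    return x / (1.0 + x)
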