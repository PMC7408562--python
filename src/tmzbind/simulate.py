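"""Seeded synthetic-data generators emulating the spectroscopic assays.

Every input class the analysis modules consume can be generated here
with known ground truth, so the whole pipeline is testable end to end
without instrument data:

* protein tryptophan emission band (Gaussian, peak near 334 nm),
* drug absorbance spectra (main band 329 nm, minor band 258 nm)
  converting into a hydrolysis-product band at 265 nm,
* quenching titrations from the Stern-Volmer or 1:1-isotherm forward
  models,
* lipid partition titrations from the saturation law,
* polarized-intensity series encoding a sigmoidal anisotropy drop
  across the bilayer melting temperature,
* first-order decay time courses.

Noise is additive Gaussian with a standard deviation stated relative
to the model's dynamic range; generation is deterministic given
(seed, parameters).  Band shapes are Gaussian by construction so that
closed-form areas are available as oracles for the integration code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .anisotropy import PolarizedReading, intensities_from_anisotropy
from .binding import QuenchTitration
from .errors import InvalidInputError, InvalidParameterError
from .kinetics import DecaySeries
from .partition import GAMMA_DEFAULT, PartitionTitration, partition_curve
from .spectra import Spectrum


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise with sigma relative to the signal scale.

    ``kind="none"`` produces exact model values regardless of seed.
    """

    kind: Literal["none", "gaussian_additive"] = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_additive"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")


NOISELESS = NoiseSpec()


def _apply_noise(values: np.ndarray, scale: float, noise: NoiseSpec) -> np.ndarray:
    if noise.kind == "none" or noise.sigma == 0.0:
        return values
    rng = np.random.default_rng(noise.seed)
    return values + rng.normal(0.0, noise.sigma * scale, size=values.shape)


def _gaussian(wl: np.ndarray, peak: float, width: float,
              amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((wl - peak) / width) ** 2)


def gen_emission_spectrum(peak_nm: float = 334.0, width_nm: float = 25.0,
                          amplitude: float = 1000.0,
                          grid: np.ndarray | None = None,
                          noise: NoiseSpec = NOISELESS) -> Spectrum:
    """Gaussian tryptophan-like emission band (default peak 334 nm, as for
    albumin's single buried Trp residue) on a 290-400 nm grid."""
    if width_nm <= 0:
        raise InvalidParameterError("width must be > 0")
    if grid is None:
        grid = np.arange(290.0, 400.0 + 0.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be strictly ascending")
    vals = _gaussian(grid, peak_nm, width_nm, amplitude)
    vals = _apply_noise(vals, amplitude, noise)
    return Spectrum(grid, vals, kind="emission", label="synthetic emission")


# Band parameters emulating the drug and hydrolysis-product chromophores:
# intact drug absorbs at 329 nm (main) and 258 nm (minor); the ring-opened
# product's amide band grows at 265 nm.
_DRUG_BANDS = ((329.0, 12.0, 1.0), (258.0, 10.0, 0.45))
_PRODUCT_BAND = (265.0, 11.0, 0.9)


def gen_drug_absorbance(fraction_degraded: float = 0.0,
                        amplitude: float = 1.0,
                        grid: np.ndarray | None = None,
                        noise: NoiseSpec = NOISELESS) -> Spectrum:
    """Drug absorbance spectrum at a stated degradation extent.

    A mixture (1 - f) x intact-drug bands + f x product band; at f = 0
    the global maximum sits at 329 nm, at f = 1 only the 265 nm product
    band remains.
    """
    f = fraction_degraded
    if not (0.0 <= f <= 1.0):
        raise InvalidParameterError("fraction_degraded must lie in [0, 1]")
    if grid is None:
        grid = np.arange(240.0, 400.0 + 0.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    vals = np.zeros_like(grid)
    for peak, width, rel in _DRUG_BANDS:
        vals += (1.0 - f) * _gaussian(grid, peak, width, rel * amplitude)
    p, w, rel = _PRODUCT_BAND
    vals += f * _gaussian(grid, p, w, rel * amplitude)
    vals = _apply_noise(vals, amplitude, noise)
    return Spectrum(grid, vals, kind="absorbance", label="synthetic absorbance")


def gen_quench_titration(model: Literal["stern_volmer", "isotherm"],
                         params: dict,
                         conc_grid: np.ndarray,
                         noise: NoiseSpec = NOISELESS,
                         temperature: float = 298.15) -> QuenchTitration:
    """Quenching titration from a forward model.

    ``stern_volmer`` params: K_SV (M^-1), I0 (default 1000).
    ``isotherm`` params: K_a (M^-1), I0 (default 1000), Ic (default 0).
    Noiseless output inverts exactly under the matching fit.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0 or conc[0] != 0.0:
        raise InvalidInputError("concentration grid must start at 0")
    I0 = float(params.get("I0", 1000.0))
    if model == "stern_volmer":
        K_SV = float(params["K_SV"])
        intensity = I0 / (1.0 + K_SV * conc)
    elif model == "isotherm":
        K_a = float(params["K_a"])
        Ic = float(params.get("Ic", 0.0))
        dI = (I0 - Ic) * conc / (1.0 / K_a + conc)
        intensity = I0 - dI
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    intensity = _apply_noise(intensity, I0, noise)
    intensity = np.maximum(intensity, I0 * 1e-9)  # intensities stay positive
    return QuenchTitration(conc, intensity, temperature=temperature, I0=I0)


def gen_partition_titration(K_p: float, gamma: float = GAMMA_DEFAULT,
                            deltaA_max: float = 0.05,
                            lipid_grid: np.ndarray | None = None,
                            noise: NoiseSpec = NOISELESS) -> PartitionTitration:
    """Absorbance-change titration from the partition saturation law."""
    if lipid_grid is None:
        lipid_grid = np.linspace(0.0, 3e-3, 8)
    lipid = np.asarray(lipid_grid, dtype=float)
    if np.any(lipid < 0):
        raise InvalidInputError("lipid concentrations must be >= 0")
    dA = partition_curve(lipid, K_p, deltaA_max, gamma)
    dA = _apply_noise(dA, deltaA_max, noise)
    return PartitionTitration(lipid, dA, molar_volume_gamma=gamma)


def gen_anisotropy_series(T_grid: np.ndarray | None = None,
                          r_low: float = 0.339, r_high: float = 0.092,
                          T_m: float = 23.0, width: float = 1.0,
                          G: float = 1.0,
                          noise: NoiseSpec = NOISELESS
                          ) -> list[PolarizedReading]:
    """Polarized-intensity series encoding a sigmoidal gel->fluid
    anisotropy drop (defaults: plateaus 0.339 and 0.092, midpoint 23 °C,
    the melting signature of DMPC bilayers probed with DPH)."""
    if T_grid is None:
        T_grid = np.arange(10.0, 37.0 + 1.0, 1.0)
    T_grid = np.asarray(T_grid, dtype=float)
    for r in (r_low, r_high):
        if not (-0.5 < r < 1.0):
            raise InvalidInputError(f"anisotropy {r} not attainable")
    r_curve = r_high + (r_low - r_high) / (1.0 + np.exp((T_grid - T_m) / width))
    rng = np.random.default_rng(noise.seed)
    readings = []
    for T, r in zip(T_grid, r_curve):
        I_VV, I_VH = intensities_from_anisotropy(float(r), G=G, I_VH=100.0)
        if noise.kind == "gaussian_additive" and noise.sigma > 0:
            I_VV += rng.normal(0.0, noise.sigma * I_VV)
            I_VH += rng.normal(0.0, noise.sigma * I_VH)
        readings.append(PolarizedReading(
            I_VV=max(I_VV, 1e-9), I_VH=max(I_VH, 1e-9), temperature=float(T),
            I_HV=G * 100.0, I_HH=100.0,
        ))
    return readings


def gen_decay_series(k: float, A0: float = 1.0, A_inf: float = 0.0,
                     t_grid: np.ndarray | None = None,
                     noise: NoiseSpec = NOISELESS,
                     label: str = "") -> DecaySeries:
    """First-order decay time course A_inf + (A0 - A_inf) e^(-kt), hours."""
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 8.0, 20)
    t = np.asarray(t_grid, dtype=float)
    sig = A_inf + (A0 - A_inf) * np.exp(-k * t)
    sig = _apply_noise(sig, A0 - A_inf if A0 > A_inf else A0, noise)
    sig = np.maximum(sig, A0 * 1e-9)
    return DecaySeries(t, sig, label=label)
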