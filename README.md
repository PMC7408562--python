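# tmzbind

Quantitative spectroscopy of temozolomide's fate in blood: binding to the
two major drug-carrying plasma proteins — human serum albumin (HSA) and
α1-acid glycoprotein (AGP) — partitioning into model lipid membranes, and
the hydrolytic degradation that limits the drug's plasma half-life.

The package is aimed at biophysical chemists and pharmacokinetic modellers
who work with fluorescence-quenching, UV-VIS and anisotropy data.  It turns
raw wavelength-indexed spectra and titration tables into the standard
binding, transfer-geometry, partitioning and kinetic parameters, and ships
a seeded synthetic-data module emulating every assay so the whole pipeline
is testable without an instrument.

## The models

**Inner-filter correction** of fluorescence intensities for an absorbing
ligand: `I_cor = I_obs · 10^((A_ex + A_em)/2)`.

**Stern–Volmer quenching**: `I₀/I = 1 + K_SV[Q]`; the apparent bimolecular
rate `k_q = K_SV/τ₀` (τ₀ = 6.4 ns for protein tryptophan) is compared with
the diffusion-collision ceiling 2×10¹⁰ M⁻¹s⁻¹ to classify the mechanism as
static (ground-state complex) or dynamic-compatible.

**1:1 binding isotherm** under ligand excess:
`ΔI = (I₀ − I_c)·[L]/(1/K_a + [L])`, giving the association constant `K_a`,
its reciprocal `K_d`, and the residual fluorescence `I_c` of the saturated
protein.  Thermodynamics follow from `ΔG = −RT ln K_a` and the van't Hoff
relation `ln K_a = −ΔH/RT + ΔS/R`.

**FRET geometry**: overlap integral `J = ∫ I(λ) ε(λ) λ⁴ dλ` (donor emission
area-normalized, ε in M⁻¹cm⁻¹, λ in nm) and Förster radius
`R₀ = 0.2108·[κ² Φ_F n⁻⁴ J]^(1/6)` Å, with the practical significance bound
`r ≤ 1.5 R₀` on the donor–acceptor distance.

**Membrane partitioning**: `ΔA = ΔA_max·[lipid]/(1/(K_p γ) + [lipid])` with
lipid molar volume γ = 0.9 M⁻¹, in fixed- or free-bound-absorbance modes
(the latter flags unidentifiable fits as upper bounds only).

**Anisotropy**: `r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)` with
`G = I_HV/I_HH`, plus a logistic fit of r(T) locating the bilayer melting
temperature.

**Hydrolysis kinetics**: `A(t) = A_∞ + (A₀ − A_∞)e^(−kt)`, `t½ = ln2/k`,
with multi-condition comparison of rate constants.

**Plasma distribution**: competitive single-site equilibrium
`f_i = K_a,i[P_i]/(1 + Σ_j K_a,j[P_j])`, optionally with finite-drug mass
balance.

## Worked example

```python
import numpy as np
from tmzbind import fit_binding_isotherm, gibbs_free_energy
from tmzbind.simulate import gen_quench_titration

conc = np.linspace(0, 4e-4, 12)                      # 0 to 400 uM ligand
t = gen_quench_titration("isotherm", {"K_a": 5103.0, "Ic": 0.0}, conc)
fit = fit_binding_isotherm(t)
print(f"K_a = {fit.K_a:.0f} M^-1, K_d = {fit.K_d*1e3:.2f} mM")
print(f"dG  = {gibbs_free_energy(fit.K_a, 298.15):.0f} J/mol")
```

prints

```
K_a = 5103 M^-1, K_d = 0.20 mM
dG  = -21160 J/mol
```

i.e. a moderate, spontaneous association: a dissociation constant of
0.2 mM and about −21 kJ/mol of binding free energy at 25 °C — the regime in
which albumin stabilizes and transports the drug without sequestering it.

The complete analysis chain lives under `analysis/` as numbered scripts
(`01_simulate_inputs.py` … `07_plasma_distribution.py`); each reads the
synthetic datasets, writes a results table under `results/`, and prints a
one-line summary of what it found.  A `tmzbind` console command exposes the
same operations on delimited-text files (`tmzbind --help`).

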