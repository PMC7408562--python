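#!/usr/bin/env python
"""Generate the synthetic instrument datasets all downstream analyses read.

Emulated conditions: a tryptophan emission band peaking at 334 nm; drug
absorbance spectra (329/258 nm bands) converting to the 265 nm hydrolysis
product; quenching titrations at the fitted Stern-Volmer and association
constants; lipid partition titrations on a 0-3 mM grid; a polarized-
intensity series with the DMPC gel->fluid anisotropy drop at 23 C; and
first-order decay courses at decreasing rates mimicking increasing
albumin protection.  Noise is photometric-scale Gaussian.
"""

from pathlib import Path

import numpy as np

from tmzbind import simulate as sim
from tmzbind import spectra, tables

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260930

noise = lambda sigma, offset: sim.NoiseSpec("gaussian_additive", sigma,
                                            SEED + offset)

spectra.write_spectrum(sim.gen_emission_spectrum(noise=noise(0.005, 0)),
                       OUT / "protein_emission.csv")
for f, name in [(0.0, "drug_fresh"), (0.5, "drug_partial"),
                (1.0, "drug_degraded")]:
    spectra.write_spectrum(sim.gen_drug_absorbance(f, noise=noise(0.005, 1)),
                           OUT / f"{name}_absorbance.csv")

conc = np.linspace(0.0, 55e-6, 12)
tables.write_quench_titration(
    sim.gen_quench_titration("stern_volmer", {"K_SV": 4837.0}, conc,
                             noise=noise(0.01, 2)),
    OUT / "quench_sv_hsa_buffer.csv")
tables.write_quench_titration(
    sim.gen_quench_titration("isotherm", {"K_a": 5103.0, "Ic": 0.0},
                             np.linspace(0.0, 4e-4, 12), noise=noise(0.01, 3)),
    OUT / "quench_isotherm_hsa_water.csv")
tables.write_quench_titration(
    sim.gen_quench_titration("isotherm",
                             {"K_a": 8184.0, "Ic": 300.0, "I0": 1000.0},
                             np.linspace(0.0, 4e-4, 12), noise=noise(0.01, 4)),
    OUT / "quench_isotherm_agp.csv")

tables.write_partition_titration(
    sim.gen_partition_titration(159.0, deltaA_max=0.05, noise=noise(0.02, 5)),
    OUT / "partition_epc.csv")
tables.write_partition_titration(
    sim.gen_partition_titration(133.0, deltaA_max=0.05, noise=noise(0.02, 6)),
    OUT / "partition_epc_chol.csv")

tables.write_polarized_series(
    sim.gen_anisotropy_series(noise=noise(0.005, 7)),
    OUT / "anisotropy_dmpc.csv")

for i, k in enumerate([0.60, 0.45, 0.30, 0.18]):
    s = sim.gen_decay_series(k, label=f"hsa_level_{i}",
                             noise=noise(0.02, 8 + i))
    tables.write_decay_series(s, OUT / f"decay_hsa_{i}.csv")

print(f"wrote synthetic datasets to {OUT}")
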