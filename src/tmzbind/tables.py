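"""Delimited-text I/O for titration and series tables.

All table files are comma- (or tab-) delimited with a mandatory header
naming the columns and optional leading ``# key: value`` comment lines
carrying metadata (e.g. ``# temperature_C: 25``).  Readers are strict
about headers and monotonic concentration columns so that malformed
instrument exports fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .anisotropy import PolarizedReading
from .binding import QuenchTitration
from .errors import InvalidInputError
from .kinetics import DecaySeries
from .partition import GAMMA_DEFAULT, PartitionTitration
from .plasma import PlasmaComposition, ProteinSite


def _read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("#"):
            if ":" in stripped:
                key, val = stripped.lstrip("# ").split(":", 1)
                meta[key.strip()] = val.strip()
            body_start = i + 1
        elif stripped:
            break
        else:
            body_start = i + 1
    body = "".join(lines[body_start:])
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    from io import StringIO

    df = pd.read_csv(StringIO(body), sep=sep)
    df.columns = [c.strip() for c in df.columns]
    return df, meta


def _write_table(df: pd.DataFrame, path: str | Path,
                 metadata: dict[str, object] | None = None) -> None:
    path = Path(path)
    header = "".join(f"# {k}: {v}\n" for k, v in (metadata or {}).items())
    path.write_text(header + df.to_csv(index=False, float_format="%.10g"))


def read_quench_titration(path: str | Path) -> QuenchTitration:
    """Read ``conc_M,intensity`` with optional ``# temperature_C`` metadata."""
    df, meta = _read_table(path)
    if list(df.columns[:2]) != ["conc_M", "intensity"]:
        raise InvalidInputError(
            f"{path}: expected header 'conc_M,intensity', got {list(df.columns)}"
        )
    temp_c = float(meta.get("temperature_C", 25.0))
    return QuenchTitration(df["conc_M"].to_numpy(), df["intensity"].to_numpy(),
                           temperature=temp_c + 273.15)


def write_quench_titration(t: QuenchTitration, path: str | Path) -> None:
    df = pd.DataFrame({"conc_M": t.quencher_conc, "intensity": t.intensity})
    _write_table(df, path, {"temperature_C": f"{t.temperature - 273.15:g}"})


def read_partition_titration(path: str | Path,
                             gamma: float = GAMMA_DEFAULT) -> PartitionTitration:
    """Read ``lipid_conc_M,delta_A``; gamma may come from metadata or caller."""
    df, meta = _read_table(path)
    if list(df.columns[:2]) != ["lipid_conc_M", "delta_A"]:
        raise InvalidInputError(
            f"{path}: expected header 'lipid_conc_M,delta_A', "
            f"got {list(df.columns)}"
        )
    if "gamma_M-1" in meta:
        gamma = float(meta["gamma_M-1"])
    return PartitionTitration(df["lipid_conc_M"].to_numpy(),
                              df["delta_A"].to_numpy(),
                              molar_volume_gamma=gamma)


def write_partition_titration(t: PartitionTitration, path: str | Path) -> None:
    df = pd.DataFrame({"lipid_conc_M": t.lipid_conc, "delta_A": t.delta_A})
    _write_table(df, path, {"gamma_M-1": f"{t.molar_volume_gamma:g}"})


def read_polarized_series(path: str | Path) -> list[PolarizedReading]:
    """Read ``temperature_C,I_VV,I_VH[,I_HV,I_HH]``."""
    df, _ = _read_table(path)
    required = ["temperature_C", "I_VV", "I_VH"]
    if list(df.columns[:3]) != required:
        raise InvalidInputError(
            f"{path}: expected header starting 'temperature_C,I_VV,I_VH', "
            f"got {list(df.columns)}"
        )
    has_g = "I_HV" in df.columns and "I_HH" in df.columns
    out = []
    for _, row in df.iterrows():
        out.append(PolarizedReading(
            I_VV=float(row["I_VV"]), I_VH=float(row["I_VH"]),
            temperature=float(row["temperature_C"]),
            I_HV=float(row["I_HV"]) if has_g else None,
            I_HH=float(row["I_HH"]) if has_g else None,
        ))
    return out


def write_polarized_series(readings: list[PolarizedReading],
                           path: str | Path) -> None:
    has_g = all(r.I_HV is not None and r.I_HH is not None for r in readings)
    data = {
        "temperature_C": [r.temperature for r in readings],
        "I_VV": [r.I_VV for r in readings],
        "I_VH": [r.I_VH for r in readings],
    }
    if has_g:
        data["I_HV"] = [r.I_HV for r in readings]
        data["I_HH"] = [r.I_HH for r in readings]
    _write_table(pd.DataFrame(data), path)


def read_decay_series(path: str | Path) -> DecaySeries:
    """Read ``time_h,signal``."""
    df, meta = _read_table(path)
    if list(df.columns[:2]) != ["time_h", "signal"]:
        raise InvalidInputError(
            f"{path}: expected header 'time_h,signal', got {list(df.columns)}"
        )
    return DecaySeries(df["time_h"].to_numpy(), df["signal"].to_numpy(),
                       label=meta.get("label", Path(path).stem))


def write_decay_series(s: DecaySeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_h": s.time, "signal": s.signal})
    _write_table(df, path, {"label": s.label} if s.label else None)


def read_plasma_composition(path: str | Path) -> PlasmaComposition:
    """Read ``name,Ka_M,conc_M`` plus optional ``# drug_conc_M`` metadata."""
    df, meta = _read_table(path)
    if list(df.columns[:3]) != ["name", "Ka_M", "conc_M"]:
        raise InvalidInputError(
            f"{path}: expected header 'name,Ka_M,conc_M', got {list(df.columns)}"
        )
    proteins = tuple(
        ProteinSite(str(r["name"]), float(r["Ka_M"]), float(r["conc_M"]))
        for _, r in df.iterrows()
    )
    drug = float(meta["drug_conc_M"]) if "drug_conc_M" in meta else None
    return PlasmaComposition(proteins, drug_conc=drug)


def write_plasma_composition(c: PlasmaComposition, path: str | Path) -> None:
    df = pd.DataFrame({
        "name": [p.name for p in c.proteins],
        "Ka_M": [p.K_a for p in c.proteins],
        "conc_M": [p.conc for p in c.proteins],
    })
    meta = {"drug_conc_M": f"{c.drug_conc:g}"} if c.drug_conc else None
    _write_table(df, path, meta)
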