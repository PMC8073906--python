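"""Plain-text readers/writers for the tabular formats the stages exchange.

All files are tab-delimited with a header row; small per-file metadata
(protein concentration, concentration unit, data kind) travels in leading
``# key = value`` comment lines so that a single file is self-describing.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .ans_binding import TitrationCurve
from .freq_fluor import FreqDomainSet
from .hdx_kinetics import KineticTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_titration",
    "write_titration",
    "read_freqdomain",
    "write_freqdomain",
]


def _read_meta(path: str | os.PathLike) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line.lstrip("#").split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_trace(trace: KineticTrace, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("time_min\tfraction\n")
        for t, y in zip(trace.t, trace.y):
            fh.write(f"{float(t)!r}\t{float(y)!r}\n")


def read_trace(path: str | os.PathLike) -> KineticTrace:
    df = _read_table(path)
    return KineticTrace(t=df["time_min"].to_numpy(), y=df["fraction"].to_numpy())


def write_titration(curve: TitrationCurve, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# p0 = {float(curve.p0)!r}\n# unit = uM\n")
        fh.write("ligand_conc\tfluorescence\n")
        for l, f in zip(curve.ligand_conc, curve.fluorescence):
            fh.write(f"{float(l)!r}\t{float(f)!r}\n")


def read_titration(path: str | os.PathLike) -> TitrationCurve:
    meta = _read_meta(path)
    if "p0" not in meta:
        raise ValueError(f"{path}: missing '# p0 = ...' metadata line")
    df = _read_table(path)
    return TitrationCurve(
        ligand_conc=df["ligand_conc"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        p0=float(meta["p0"]),
        unit=meta.get("unit", "uM"),
    )


def write_freqdomain(data: FreqDomainSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind = {data.kind}\n")
        fh.write("freq_MHz\tphase_deg\tmodulation\tsigma_phase\tsigma_mod\n")
        sp = data.sigma_phase if data.sigma_phase is not None else np.full_like(data.freq, np.nan)
        sm = data.sigma_mod if data.sigma_mod is not None else np.full_like(data.freq, np.nan)
        for row in zip(data.freq, data.phase, data.modulation, sp, sm):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_freqdomain(path: str | os.PathLike) -> FreqDomainSet:
    meta = _read_meta(path)
    df = _read_table(path)
    sp = df["sigma_phase"].to_numpy() if "sigma_phase" in df else None
    sm = df["sigma_mod"].to_numpy() if "sigma_mod" in df else None
    if sp is not None and np.all(np.isnan(sp)):
        sp = None
    if sm is not None and np.all(np.isnan(sm)):
        sm = None
    return FreqDomainSet(
        freq=df["freq_MHz"].to_numpy(),
        phase=df["phase_deg"].to_numpy(),
        modulation=df["modulation"].to_numpy(),
        sigma_phase=sp,
        sigma_mod=sm,
        kind=meta.get("kind", "intensity"),
    )
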