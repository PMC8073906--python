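"""Reduce macromolecular structure files to the Cα point model.

The contact-network analysis treats a protein as the ordered set of its
α-carbon positions. This module reads PDB / mmCIF files (via gemmi),
keeps one Cα per amino-acid residue, and resolves the usual crystallographic
noise: alternate locations (highest occupancy wins, ties broken by altloc
identifier), selenomethionine-style substitutions (mapped back to canonical
names), heteroatoms / waters / ligands (dropped).

Coordinates are kept in Å everywhere; nothing downstream converts units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Residue",
    "CalphaStructure",
    "StructureError",
    "load_calpha",
    "STANDARD_AA",
    "NONSTANDARD_TO_CANONICAL",
]


class StructureError(ValueError):
    """Raised for unreadable files, absent chains or empty selections."""


STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# modified residues that still carry a backbone Cα and have an unambiguous
# canonical parent; anything not listed here is skipped with a warning
NONSTANDARD_TO_CANONICAL = {
    "MSE": "MET",  # selenomethionine
    "FME": "MET",
    "SEC": "CYS",  # selenocysteine (closest Cα-level analogue)
    "CSO": "CYS",
    "CME": "CYS",
    "OCS": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "HYP": "PRO",
    "MLY": "LYS",
    "M3L": "LYS",
    "KCX": "LYS",
    "PCA": "GLU",
}


@dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    coord: tuple[float, float, float]

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class CalphaStructure:
    """Ordered list of residues with α-carbon coordinates (Å)."""

    residues: list[Residue]
    skipped_no_ca: int = 0
    skipped_unknown: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate (chain, resnum, icode) triples")
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in Å, in file order."""
        if not self.residues:
            return np.zeros((0, 3))
        return np.array([r.coord for r in self.residues], dtype=float)

    @property
    def node_ids(self) -> list[tuple[str, int, str]]:
        return [r.id for r in self.residues]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r.chain_id for r in self.residues],
                "resnum": [r.residue_number for r in self.residues],
                "icode": [r.insertion_code for r in self.residues],
                "resname": [r.residue_name for r in self.residues],
                "x": [r.coord[0] for r in self.residues],
                "y": [r.coord[1] for r in self.residues],
                "z": [r.coord[2] for r in self.residues],
            }
        )

    def write_table(self, path: str | os.PathLike) -> None:
        """Plain tab-delimited coordinate table (lossless round trip)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_table(cls, path: str | os.PathLike) -> "CalphaStructure":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"icode": str})
        residues = [
            Residue(
                chain_id=str(row.chain),
                residue_number=int(row.resnum),
                insertion_code=str(row.icode),
                residue_name=str(row.resname),
                coord=(float(row.x), float(row.y), float(row.z)),
            )
            for row in df.itertuples()
        ]
        return cls(residues=residues)

    def write_pdb(self, path: str | os.PathLike) -> None:
        """Minimal single-model PDB with one CA atom per residue."""
        with open(path, "w") as fh:
            for i, r in enumerate(self.residues, start=1):
                x, y, z = r.coord
                fh.write(
                    f"ATOM  {i:5d}  CA  {r.residue_name:<3s} {r.chain_id[:1]}"
                    f"{r.residue_number:4d}{(r.insertion_code or ' ')[:1]}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("END\n")


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy Cα; occupancy ties broken by altloc identifier."""
    cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc or ""))


def load_calpha(
    path: str | os.PathLike,
    chains: Sequence[str] | None = None,
    model_index: int = 0,
) -> CalphaStructure:
    """Read a PDB or mmCIF file into a :class:`CalphaStructure`.

    Parameters
    ----------
    path:
        Structure file; format inferred from contents/extension by gemmi.
    chains:
        Optional chain ids to keep. Absent chains raise a
        :class:`StructureError` listing the ones available.
    model_index:
        Which model of a multi-model file to read (default: first).

    Only residues whose name is one of the 20 canonical amino acids, or maps
    to one via :data:`NONSTANDARD_TO_CANONICAL`, are kept. Waters, ligands
    and other heteroatoms are excluded. Residues that should carry a Cα but
    do not are counted in ``skipped_no_ca``.
    """
    if not os.path.exists(path):
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if model_index >= len(st):
        raise StructureError(
            f"model_index {model_index} out of range; file has {len(st)} model(s)"
        )
    model = st[model_index]
    available = [ch.name for ch in model]
    selected: Iterable[gemmi.Chain]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise StructureError(
                f"chain(s) {missing} not present; available chains: {available}"
            )
        selected = [ch for ch in model if ch.name in set(chains)]
    else:
        selected = list(model)

    residues: list[Residue] = []
    skipped_no_ca = 0
    skipped_unknown = 0
    warnings: list[str] = []
    for chain in selected:
        for res in chain:
            name = res.name
            if name in STANDARD_AA:
                canon = name
            elif name in NONSTANDARD_TO_CANONICAL:
                canon = NONSTANDARD_TO_CANONICAL[name]
            else:
                # polymer (ATOM-record) residue we cannot map -> warn; plain
                # heteroatoms (waters, heme, ligands) are silently excluded
                if res.het_flag == "A":
                    skipped_unknown += 1
                    warnings.append(f"unmapped polymer residue {name} {res.seqid}")
                continue
            ca = _pick_ca(res)
            if ca is None:
                skipped_no_ca += 1
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=icode,
                    residue_name=canon,
                    coord=(ca.pos.x, ca.pos.y, ca.pos.z),
                )
            )
    if not residues:
        raise StructureError(
            f"no amino-acid residues with Cα found in {path} "
            f"(chains={chains}, model={model_index})"
        )
    return CalphaStructure(
        residues=residues,
        skipped_no_ca=skipped_no_ca,
        skipped_unknown=skipped_unknown,
        warnings=warnings,
    )
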