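"""PDB and FASTA input/output for backbone structures.

Only ATOM records for the four backbone atoms N, CA, C, O are read or
written; structures with missing backbone atoms, CA-only traces or
non-canonical residues are rejected with a clear error.  Written files use
chain ID "A", occupancy 1.00 and B-factor 0.00.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from Bio.PDB import PDBParser

from .chain import AMINO_ACIDS, ATOM_NAMES, Chain, Conformation, measure_dihedrals

__all__ = ["SourceStructure", "read_pdb", "write_pdb", "read_fasta", "write_conformation"]


@dataclass(frozen=True)
class SourceStructure:
    """A backbone structure with its sequence, as excised from a PDB file or
    built synthetically; the raw material for fragment libraries."""

    structure_id: str
    sequence: str
    coords: np.ndarray  # (n, 4, 3), atoms N, CA, C, O

    @property
    def n(self) -> int:
        return len(self.sequence)

    def dihedrals(self) -> np.ndarray:
        return measure_dihedrals(self.coords)


class PDBError(ValueError):
    """Unusable PDB content (missing backbone atoms, unknown residues)."""


def read_pdb(path) -> SourceStructure:
    """Read the first chain of the first model of a PDB file.

    Requires all four backbone atoms per residue; HETATM records and waters
    are ignored.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    seq = []
    xyz = []
    for res in chain.get_residues():
        if res.id[0] != " ":  # skip HETATM/water
            continue
        resname = res.get_resname().capitalize()
        if resname not in protein_letters_3to1:
            raise PDBError(f"{path.name}: non-canonical residue {res.get_resname()}")
        missing = [a for a in ATOM_NAMES if a not in res]
        if missing:
            raise PDBError(
                f"{path.name}: residue {res.id[1]} is missing backbone "
                f"atom(s) {missing}; CA-only or incomplete backbones are not supported"
            )
        seq.append(protein_letters_3to1[resname])
        xyz.append([res[a].get_coord() for a in ATOM_NAMES])
    if len(seq) < 3:
        raise PDBError(f"{path.name}: fewer than 3 usable residues")
    return SourceStructure(path.stem, "".join(seq), np.asarray(xyz, dtype=float))


def write_pdb(path, sequence: str, coords: np.ndarray) -> None:
    """Write a backbone-only PDB file (ATOM records, chain A)."""
    coords = np.asarray(coords, dtype=float)
    n = len(sequence)
    if coords.shape != (n, 4, 3):
        raise PDBError(f"coords shape {coords.shape} does not match sequence length {n}")
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise PDBError(f"non-canonical residue code {aa!r}")
        res3 = protein_letters_1to3[aa].upper()
        for j, atom in enumerate(ATOM_NAMES):
            x, y, z = coords[i, j]
            lines.append(
                f"ATOM  {serial:5d} {atom:^4s} {res3:>3s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_conformation(path, conf: Conformation) -> None:
    write_pdb(path, conf.chain.sequence, conf.coords)


def read_conformation(path) -> Conformation:
    """Read a backbone PDB into a Conformation (dihedrals measured from the
    coordinates; the rebuilt ideal-geometry coordinates are used)."""
    src = read_pdb(path)
    return Conformation(Chain(src.sequence), src.dihedrals())


def read_fasta(path) -> Chain:
    """Read the first record of a FASTA file as the target chain."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return Chain(str(records[0].seq).upper())
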