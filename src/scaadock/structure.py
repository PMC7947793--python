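"""Lightweight molecular containers and PDB I/O.

Structures are plain atom/residue containers with numpy coordinates in
Ångström; reading and writing of PDB v3.3 goes through Bio.PDB.
Hydrogens are never stored — the whole pipeline works on heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "write_pdb",
    "write_multimodel_pdb",
]

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) float64, Å
    charge: float | None = None  # partial charge, e units; None = unannotated

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    name: str  # three-letter code
    resseq: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = " "
    meta: dict = field(default_factory=dict)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Structure:
    """An ordered collection of residues (possibly several chains)."""

    residues: list[Residue] = field(default_factory=list)
    id: str = "model"
    meta: dict = field(default_factory=dict)

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n, 3) array, residue order."""
        if self.n_atoms == 0:
            return np.empty((0, 3))
        return np.vstack([a.coord for a in self.atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_atoms, 3)}, got {coords.shape}")
        for atom, xyz in zip(self.atoms(), coords):
            atom.coord = xyz.copy()

    def ca_coords(self) -> np.ndarray:
        return self.atom_coords("CA")

    def atom_coords(self, name: str) -> np.ndarray:
        rows = [r.atom(name).coord for r in self.residues if r.atom(name) is not None]
        return np.vstack(rows) if rows else np.empty((0, 3))

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain, []).append(r)
        return out

    def get_residue(self, chain: str, resseq: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.resseq == resseq:
                return r
        raise KeyError(f"no residue {resseq} in chain {chain!r}")

    def get_atom(self, chain: str, resseq: int, name: str) -> Atom:
        atom = self.get_residue(chain, resseq).atom(name)
        if atom is None:
            raise KeyError(f"no atom {name} in {chain}/{resseq}")
        return atom

    def atom_index(self, chain: str, resseq: int, name: str) -> int:
        """Flat index of an atom into the ``coords()`` array."""
        i = 0
        for r in self.residues:
            for a in r.atoms:
                if r.chain == chain and r.resseq == resseq and a.name == name:
                    return i
                i += 1
        raise KeyError(f"no atom {name} in {chain}/{resseq}")

    def copy(self) -> "Structure":
        return Structure(
            residues=[
                Residue(
                    name=r.name,
                    resseq=r.resseq,
                    chain=r.chain,
                    atoms=[Atom(a.name, a.element, a.coord.copy(), a.charge) for a in r.atoms],
                    icode=r.icode,
                    meta=dict(r.meta),
                )
                for r in self.residues
            ],
            id=self.id,
            meta=dict(self.meta),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy (x' = R x + t)."""
        out = self.copy()
        out.set_coords(self.coords() @ np.asarray(rotation).T + np.asarray(translation))
        return out


def _to_biopdb(structures: Iterable[Structure], sid: str = "S"):
    builder = StructureBuilder()
    builder.init_structure(sid)
    for imodel, struct in enumerate(structures):
        builder.init_model(imodel)
        seen_chains: set[str] = set()
        serial = 1
        for res in struct.residues:
            if res.chain not in seen_chains:
                builder.init_chain(res.chain)
                seen_chains.add(res.chain)
            builder.init_seg("    ")
            builder.init_residue(res.name, " ", res.resseq, res.icode)
            for atom in res.atoms:
                builder.init_atom(
                    atom.name, atom.coord.astype(float), 0.0, 1.0, " ",
                    atom.name.center(4) if len(atom.name) < 4 else atom.name,
                    serial, atom.element,
                )
                serial += 1
    return builder.get_structure()


def write_pdb(structure: Structure, path, header_lines: Iterable[str] = ()) -> None:
    """Write one structure as a PDB v3.3 file (optional REMARK header)."""
    write_multimodel_pdb([structure], path, header_lines=header_lines)


def write_multimodel_pdb(
    structures: list[Structure], path, header_lines: Iterable[str] = ()
) -> None:
    """Write several structures as MODEL/ENDMDL blocks of one PDB file."""
    io = PDBIO()
    io.set_structure(_to_biopdb(structures))
    tmp = str(path)
    io.save(tmp)
    if header_lines:
        with open(tmp) as fh:
            body = fh.read()
        with open(tmp, "w") as fh:
            for line in header_lines:
                fh.write(f"REMARK 250 {line}\n")
            fh.write(body)


def read_structure(pdb_path, chain_filter: Iterable[str] | None = None) -> Structure:
    """Read heavy protein atoms from a PDB file.

    Waters and HETATM records are dropped; for disordered atoms the
    highest-occupancy conformer is kept (altloc 'A' on ties); insertion
    codes are preserved; hydrogens are discarded.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("in", str(pdb_path)).get_models())
    wanted = set(chain_filter) if chain_filter else None
    out = Structure(id=str(pdb_path))
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for res in chain:
            het, resseq, icode = res.id
            if het != " ":  # waters and heteroatoms
                continue
            atoms = []
            for atom in res:
                if atom.is_disordered():
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-a.get_occupancy(), a.get_altloc() != "A"),
                    )
                    atom = children[0]
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(Atom(atom.get_name(), element or atom.get_name()[0],
                                  np.asarray(atom.get_coord(), dtype=float)))
            if atoms:
                out.residues.append(
                    Residue(res.get_resname(), resseq, chain.id, atoms, icode)
                )
    return out
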