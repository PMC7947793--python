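"""All-atom rigid peptide construction from sequence and Φ/Ψ dihedrals.

Backbones are grown by natural-extension-of-reference-frame (NeRF)
placement from canonical Engh–Huber-style bond lengths and angles, so
every bond length is exact by construction and the measured Φ/Ψ of the
built chain reproduce the requested values.  Sidechains are attached
from ideal internal-coordinate templates with χ angles taken from a
single most-common-rotamer table (χ = 180° where no entry exists).

The frame convention for the first residue: N at the origin, CA on the
+x axis, C in the xy-plane.  Only heavy atoms are built; histidine is
tagged as the doubly N-protonated (+1) tautomer in residue metadata.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AntigenTemplate, default_template
from .geometry import measure_dihedral, normalize_angle, place_atom
from .structure import ONE_TO_THREE, Atom, Residue, Structure

__all__ = [
    "BACKBONE",
    "ResidueDihedrals",
    "DihedralTable",
    "default_dihedrals",
    "build_backbone",
    "attach_sidechains",
    "build_peptide",
    "build_library_peptide",
    "backbone_dihedrals",
]

#: Canonical backbone geometry (lengths in Å, angles in degrees).
BACKBONE = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "CA_CB": 1.530,
    "ang_N_CA_C": 111.2,
    "ang_CA_C_N": 116.2,
    "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.8,
    "ang_N_CA_CB": 110.4,
    # torsion C-N-CA-CB giving L chirality (improper N-CA-C-CB ≈ -123°)
    "tor_C_N_CA_CB": -122.55,
}


@dataclass(frozen=True)
class ResidueDihedrals:
    """Backbone torsions of one residue, degrees, normalized to (-180, 180]."""

    phi: float
    psi: float
    omega: float = 180.0  # trans peptide bond

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", normalize_angle(self.phi))
        object.__setattr__(self, "psi", normalize_angle(self.psi))
        object.__setattr__(self, "omega", normalize_angle(self.omega))


@dataclass(frozen=True)
class DihedralTable:
    """Per-position backbone dihedrals for a scaffold of fixed length."""

    entries: tuple[ResidueDihedrals, ...]
    provenance: str = "user"

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> ResidueDihedrals:
        return self.entries[i]

    @classmethod
    def uniform(cls, length: int, phi: float, psi: float, omega: float = 180.0,
                provenance: str = "uniform") -> "DihedralTable":
        return cls(tuple(ResidueDihedrals(phi, psi, omega) for _ in range(length)),
                   provenance)

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "DihedralTable":
        """Read a (position, phi, psi, omega) CSV, sorted by position."""
        with open(path, newline="") as fh:
            rows = sorted(csv.DictReader(fh), key=lambda r: int(r["position"]))
        entries = tuple(
            ResidueDihedrals(float(r["phi"]), float(r["psi"]),
                             float(r.get("omega", 180.0) or 180.0))
            for r in rows
        )
        return cls(entries, provenance or str(path))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["position", "phi", "psi", "omega"])
            for i, e in enumerate(self.entries, start=1):
                w.writerow([i, e.phi, e.psi, e.omega])


def default_dihedrals() -> DihedralTable:
    """The packaged extended β-like scaffold (φ=-139°, ψ=135° throughout).

    A stand-in for experimentally derived MHC-groove dihedrals; real
    tables are supplied per receptor via :meth:`DihedralTable.from_csv`.
    """
    ref = resources.files("scaadock.data").joinpath("dihedrals_default.csv")
    with resources.as_file(ref) as path:
        return DihedralTable.from_csv(path, provenance="builtin extended scaffold")


def build_backbone(sequence: str, dihedrals: DihedralTable, chain: str = "A") -> Structure:
    """Grow an N/CA/C/O backbone for ``sequence`` at the given dihedrals."""
    if len(sequence) != len(dihedrals):
        raise ValueError(
            f"sequence length {len(sequence)} != dihedral table length {len(dihedrals)}"
        )
    for code in sequence:
        if code not in ONE_TO_THREE:
            raise ValueError(f"invalid residue code {code!r}")

    b = BACKBONE
    struct = Structure(id=sequence)
    prev = None  # (N, CA, C) of previous residue
    for i, code in enumerate(sequence):
        d = dihedrals[i]
        if prev is None:
            n = np.zeros(3)
            ca = np.array([b["N_CA"], 0.0, 0.0])
            theta = np.radians(b["ang_N_CA_C"])
            c = ca + b["CA_C"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
        else:
            pn, pca, pc = prev
            n = place_atom(pn, pca, pc, b["C_N"], b["ang_CA_C_N"], dihedrals[i - 1].psi)
            ca = place_atom(pca, pc, n, b["N_CA"], b["ang_C_N_CA"], d.omega)
            c = place_atom(pc, n, ca, b["CA_C"], b["ang_N_CA_C"], d.phi)
        # carbonyl O in the peptide plane, anti to the next amide N
        o = place_atom(n, ca, c, b["C_O"], b["ang_CA_C_O"], normalize_angle(d.psi + 180.0))
        struct.residues.append(
            Residue(
                name=ONE_TO_THREE[code],
                resseq=i + 1,
                chain=chain,
                atoms=[
                    Atom("N", "N", n),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c),
                    Atom("O", "O", o),
                ],
            )
        )
        prev = (n, ca, c)
    return struct


def _chi(k: int, offset: float = 0.0):
    return ("chi", k, offset)


# Sidechain internal-coordinate templates beyond CB, per three-letter code:
# (atom, element, (ref_a, ref_b, ref_c), bond Å, angle °, torsion ° or χ slot).
# Values are ideal-geometry averages; ring torsions of 0/180 make aromatic
# rings exactly planar by construction.
SIDECHAINS: Mapping[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, 122.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2)),
    ],
    "SER": [
        ("OG", "O", ("N", "CA", "CB"), 1.417, 111.1, _chi(1)),
    ],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
    ],
    "CYS": [
        ("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, _chi(1)),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3)),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.7, _chi(4)),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("NE", "N", ("CB", "CG", "CD"), 1.461, 111.8, _chi(3)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.4, _chi(4)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "HIS": [  # doubly N-protonated imidazolium (+1), ring planar
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.354, 129.7, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.320, 109.2, 180.0),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 119.9, 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 127.0, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.3, 180.0),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.398, 122.4, 180.0),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.372, 117.5, 180.0),
    ],
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, _chi(2)),
    ],
}

#: Single most-common rotamer χ angles per residue; missing slots fall
#: back to 180° (trans).
DEFAULT_ROTAMERS: Mapping[str, tuple[float, ...]] = {
    "VAL": (175.0,),
    "LEU": (-65.0, 175.0),
    "ILE": (-65.0, 170.0),
    "SER": (64.0,),
    "THR": (62.0,),
    "CYS": (-65.0,),
    "ASP": (-70.0, -15.0),
    "ASN": (-65.0, -60.0),
    "GLU": (-67.0, 180.0, -10.0),
    "GLN": (-67.0, 180.0, -25.0),
    "HIS": (-63.0, -74.0),
    "PHE": (-65.0, 90.0),
    "TYR": (-65.0, 90.0),
    "TRP": (-65.0, 95.0),
    "PRO": (30.0, -35.0),
}


def _resolve_torsion(spec, chis: Sequence[float]) -> float:
    if isinstance(spec, tuple) and spec[0] == "chi":
        _, k, offset = spec
        base = chis[k - 1] if k <= len(chis) else 180.0
        return normalize_angle(base + offset)
    return float(spec)


def attach_sidechains(
    structure: Structure,
    rotamer_policy: Mapping[str, Sequence[float]] | None = None,
) -> Structure:
    """Add CB and all heavy sidechain atoms to a backbone-only structure.

    ``rotamer_policy`` maps three-letter residue names to χ-angle tuples
    and overrides the built-in most-common-rotamer table.
    """
    b = BACKBONE
    policy = dict(DEFAULT_ROTAMERS)
    if rotamer_policy:
        policy.update({k: tuple(v) for k, v in rotamer_policy.items()})
    out = structure.copy()
    for res in out.residues:
        if res.name not in SIDECHAINS:
            raise ValueError(f"unknown residue {res.name!r}")
        if res.name == "GLY":
            continue
        n, ca, c = (res.atom(x).coord for x in ("N", "CA", "C"))
        cb = place_atom(c, n, ca, b["CA_CB"], b["ang_N_CA_CB"], b["tor_C_N_CA_CB"])
        res.atoms.append(Atom("CB", "C", cb))
        chis = policy.get(res.name, ())
        placed = {"N": n, "CA": ca, "C": c, "CB": cb}
        for name, element, (ra, rb, rc), bond, angle, tspec in SIDECHAINS[res.name]:
            coord = place_atom(placed[ra], placed[rb], placed[rc],
                               bond, angle, _resolve_torsion(tspec, chis))
            placed[name] = coord
            res.atoms.append(Atom(name, element, coord))
        if res.name == "HIS":
            res.meta["protonation"] = "imidazolium(+1), both ring N protonated"
    return out


def build_peptide(
    sequence: str,
    dihedrals: DihedralTable | None = None,
    rotamer_policy: Mapping[str, Sequence[float]] | None = None,
    chain: str = "A",
) -> Structure:
    """Backbone plus sidechains in one call."""
    dihedrals = dihedrals or default_dihedrals()
    if len(dihedrals) != len(sequence):
        if dihedrals.provenance == "builtin extended scaffold":
            dihedrals = DihedralTable.uniform(len(sequence), -139.0, 135.0,
                                              provenance=dihedrals.provenance)
        else:
            raise ValueError(
                f"dihedral table length {len(dihedrals)} != sequence length {len(sequence)}"
            )
    return attach_sidechains(build_backbone(sequence, dihedrals, chain), rotamer_policy)


def build_library_peptide(
    triad: Sequence[str],
    template: AntigenTemplate | None = None,
    dihedrals: DihedralTable | None = None,
    rotamer_policy: Mapping[str, Sequence[float]] | None = None,
) -> Structure:
    """Build one library member from its SCAA triad on the shared scaffold."""
    template = template or default_template()
    sequence = template.render(triad)
    struct = build_peptide(sequence, dihedrals, rotamer_policy)
    struct.meta["triad"] = tuple(triad)
    struct.id = sequence
    return struct


def backbone_dihedrals(structure: Structure) -> list[ResidueDihedrals]:
    """Measure Φ/Ψ/ω of a built chain (NaN where undefined at termini)."""
    res = structure.residues
    out = []
    for i in range(len(res)):
        get = lambda j, name: res[j].atom(name).coord
        phi = psi = omega = float("nan")
        if i > 0:
            phi = measure_dihedral(get(i - 1, "C"), get(i, "N"), get(i, "CA"), get(i, "C"))
            omega = measure_dihedral(get(i - 1, "CA"), get(i - 1, "C"), get(i, "N"), get(i, "CA"))
        if i < len(res) - 1:
            psi = measure_dihedral(get(i, "N"), get(i, "CA"), get(i, "C"), get(i + 1, "N"))
        out.append(ResidueDihedrals(phi, psi, omega) if not (
            np.isnan(phi) or np.isnan(psi) or np.isnan(omega)
        ) else _loose_dihedrals(phi, psi, omega))
    return out


def _loose_dihedrals(phi, psi, omega):
    obj = object.__new__(ResidueDihedrals)
    object.__setattr__(obj, "phi", phi)
    object.__setattr__(obj, "psi", psi)
    object.__setattr__(obj, "omega", omega)
    return obj
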