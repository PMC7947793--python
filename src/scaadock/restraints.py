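"""Ambiguous interaction restraints (AIRs) anchoring the antigen to the TCR.

An AIR aggregates several candidate atom pairs into one effective
distance d_eff = (Σ d⁻⁶)^(-1/6) and penalizes it with a flat-bottom
soft-square potential, zero inside [lower, upper].  The default scheme
ties the peptide's P2–P4 stretch to the CDR3α loop center and P4–P6 to
the CDR3β center with bounds of 4–8 Å, mimicking how the MHC groove
positions the antigen between the two hypervariable loops.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .structure import Structure

__all__ = [
    "AtomSelector",
    "AmbiguousRestraint",
    "LoopRange",
    "ReceptorAnnotation",
    "make_default_airs",
    "effective_distance",
    "restraint_energy",
    "export_air_table",
    "restraints_to_json",
    "restraints_from_json",
]

logger = logging.getLogger(__name__)

DEFAULT_LOWER = 4.0  # Å
DEFAULT_UPPER = 8.0  # Å
DEFAULT_FORCE_CONSTANT = 50.0  # kcal mol^-1 Å^-2


@dataclass(frozen=True)
class AtomSelector:
    """Names exactly one atom: chain, residue number, atom name."""

    chain: str
    resseq: int
    name: str

    def resolve(self, structure: Structure) -> np.ndarray:
        return structure.get_atom(self.chain, self.resseq, self.name).coord


@dataclass(frozen=True)
class LoopRange:
    """An annotated loop: chain plus inclusive residue-number range."""

    chain: str
    first: int
    last: int

    @property
    def center(self) -> int:
        """Central residue number; lower median for even-length ranges."""
        return (self.first + self.last) // 2


@dataclass(frozen=True)
class ReceptorAnnotation:
    cdr3a: LoopRange
    cdr3b: LoopRange


@dataclass(frozen=True)
class AmbiguousRestraint:
    """Flat-bottom distance restraint over an ambiguous set of atom pairs."""

    pairs: tuple[tuple[AtomSelector, AtomSelector], ...]
    lower: float = DEFAULT_LOWER
    upper: float = DEFAULT_UPPER
    force_constant: float = DEFAULT_FORCE_CONSTANT
    label: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("a restraint needs at least one atom pair")
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"bounds must satisfy 0 < lower < upper, got [{self.lower}, {self.upper}]"
            )


def _ligand_selector(ligand: Structure, position: int, name: str):
    """Selector for a template-position atom, degrading CB->CA on glycine."""
    res = ligand.residues[position - 1]
    if name == "CB" and res.atom("CB") is None:
        logger.warning(
            "P%d (%s) has no CB; restraint pair degraded to CA", position, res.name
        )
        name = "CA"
    return AtomSelector(res.chain, res.resseq, name)


def make_default_airs(
    ligand: Structure,
    annotation: ReceptorAnnotation,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
    split: bool = False,
) -> list[AmbiguousRestraint]:
    """The default two-restraint AIR scheme.

    Restraint A: {P2 Cα, P3 Cβ, P4 Cα} -> CDR3α-center Cα.
    Restraint B: {P4 Cα, P5 Cβ, P6 Cα} -> CDR3β-center Cα.
    With ``split=True`` every pair becomes its own single-pair restraint.
    """
    if len(ligand.residues) < 6:
        raise ValueError(
            f"ligand has {len(ligand.residues)} residues; the AIR scheme needs P2..P6"
        )
    groups = [
        ("CDR3a", annotation.cdr3a, [(2, "CA"), (3, "CB"), (4, "CA")]),
        ("CDR3b", annotation.cdr3b, [(4, "CA"), (5, "CB"), (6, "CA")]),
    ]
    out: list[AmbiguousRestraint] = []
    for label, loop, lig_spec in groups:
        rec_sel = AtomSelector(loop.chain, loop.center, "CA")
        pairs = tuple(
            (_ligand_selector(ligand, pos, name), rec_sel) for pos, name in lig_spec
        )
        if split:
            out.extend(
                AmbiguousRestraint((p,), lower, upper, force_constant,
                                   label=f"{label}:P{lig_spec[i][0]}{p[0].name}")
                for i, p in enumerate(pairs)
            )
        else:
            out.append(AmbiguousRestraint(pairs, lower, upper, force_constant, label=label))
    return out


def effective_distance(
    restraint: AmbiguousRestraint, ligand: Structure, receptor: Structure
) -> float:
    """r⁻⁶-aggregated effective distance over the restraint's pairs.

    Never exceeds the minimum pairwise distance; equals it for a single
    pair.  Adding pairs can only decrease it.
    """
    d6 = 0.0
    for lig_sel, rec_sel in restraint.pairs:
        d = float(np.linalg.norm(lig_sel.resolve(ligand) - rec_sel.resolve(receptor)))
        d6 += d ** -6
    return d6 ** (-1.0 / 6.0)


def restraint_energy(restraint: AmbiguousRestraint, d_eff: float) -> float:
    """Flat-bottom soft-square penalty in kcal/mol: zero on [lower, upper]."""
    if d_eff <= 0:
        raise ValueError(f"effective distance must be positive, got {d_eff}")
    if d_eff > restraint.upper:
        return restraint.force_constant * (d_eff - restraint.upper) ** 2
    if d_eff < restraint.lower:
        return restraint.force_constant * (restraint.lower - d_eff) ** 2
    return 0.0


def _selection(sel: AtomSelector) -> str:
    return f"(segid {sel.chain} and resid {sel.resseq} and name {sel.name})"


def export_air_table(restraints: Sequence[AmbiguousRestraint]) -> str:
    """Render restraints as ambiguity-driven-docking ``assign`` statements.

    Bounds [lower, upper] are written as center/minus/plus, e.g. [4, 8]
    becomes ``6.0 2.0 2.0``.  One statement per restraint; multi-pair
    restraints express their ambiguity as an ``or`` group of ligand
    selections.  Output is bit-stable for fixed input.
    """
    lines = []
    for r in restraints:
        lig_sels = [_selection(p[0]) for p in r.pairs]
        lig = lig_sels[0] if len(lig_sels) == 1 else "(" + " or ".join(lig_sels) + ")"
        rec = _selection(r.pairs[0][1])
        center = (r.lower + r.upper) / 2.0
        lines.append(
            f"assign {lig} {rec} {center:.1f} {center - r.lower:.1f} {r.upper - center:.1f}"
        )
    return "\n".join(lines) + "\n"


def restraints_to_json(restraints: Sequence[AmbiguousRestraint]) -> str:
    return json.dumps([asdict(r) for r in restraints], indent=2)


def restraints_from_json(text: str) -> list[AmbiguousRestraint]:
    out = []
    for obj in json.loads(text):
        pairs = tuple(
            (AtomSelector(**p[0]), AtomSelector(**p[1])) for p in obj["pairs"]
        )
        out.append(
            AmbiguousRestraint(
                pairs, obj["lower"], obj["upper"], obj["force_constant"],
                obj.get("label", ""),
            )
        )
    return out
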