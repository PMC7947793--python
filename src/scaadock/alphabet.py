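"""Simplified chemical alphabet (SCAA) and triad/template projection.

The SCAA contracts the 20 natural amino acids into six class
representatives:

====== ================= ==========================
letter chemical class    members (default table)
====== ================= ==========================
D      negative          D, E
Q      polar-amide       N, Q
H      positive          H, K, R
S      polar-hydroxyl    C, S, T
Y      aromatic          F, W, Y
V      hydrophobic       A, G, I, L, M, P, V
====== ================= ==========================

Antigen positions are numbered P1..P9 from the N terminus.  Positions
P3, P5 and P8 form the immunogenic triad (the residues facing the TCR);
every other position is an inert glycine spacer, giving nonamers of the
form ``GGXGXGGXG``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SCAA_LETTERS",
    "NATURAL_CODES",
    "CLASS_LABELS",
    "TranslationTable",
    "AntigenTemplate",
    "default_table",
    "default_template",
    "translate_residue",
    "translate_triad",
    "project_to_template",
    "unique_translated_set",
    "expand_to_natural",
]

#: The six SCAA class representatives.
SCAA_LETTERS = frozenset("DQHSYV")

#: The 20 standard one-letter amino-acid codes.
NATURAL_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Chemical-class name of each SCAA representative.
CLASS_LABELS: Mapping[str, str] = {
    "D": "negative",
    "Q": "polar-amide",
    "H": "positive",
    "S": "polar-hydroxyl",
    "Y": "aromatic",
    "V": "hydrophobic",
}


@dataclass(frozen=True)
class TranslationTable:
    """A 20 -> 6 reduced-alphabet mapping.

    Parameters
    ----------
    mapping
        One entry per standard one-letter code; values must be SCAA
        letters.  The six SCAA letters must map to themselves so that
        translation is idempotent.
    class_labels
        Human-readable chemical-class name per SCAA letter.
    """

    mapping: Mapping[str, str]
    class_labels: Mapping[str, str] = field(default_factory=lambda: dict(CLASS_LABELS))

    def __post_init__(self) -> None:
        keys = frozenset(self.mapping)
        if keys != NATURAL_CODES:
            missing = sorted(NATURAL_CODES - keys)
            extra = sorted(keys - NATURAL_CODES)
            raise ValueError(
                f"translation table must cover exactly the 20 standard codes; "
                f"missing {missing}, unexpected {extra}"
            )
        bad = {k: v for k, v in self.mapping.items() if v not in SCAA_LETTERS}
        if bad:
            raise ValueError(f"non-SCAA image letters: {bad}")
        fixed = {s for s in SCAA_LETTERS if self.mapping[s] != s}
        if fixed:
            raise ValueError(
                f"SCAA letters must be fixed points of the mapping; violated by {sorted(fixed)}"
            )

    def __getitem__(self, code: str) -> str:
        return self.mapping[code]

    @classmethod
    def from_csv(cls, path) -> "TranslationTable":
        """Load a two-column (natural_code, scaa_code) CSV table."""
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        mapping = {r["natural_code"].strip(): r["scaa_code"].strip() for r in rows}
        return cls(mapping=mapping)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["natural_code", "scaa_code"])
            for code in sorted(self.mapping):
                writer.writerow([code, self.mapping[code]])


def default_table() -> TranslationTable:
    """The packaged default SCAA translation table."""
    ref = resources.files("scaadock.data").joinpath("scaa_table.csv")
    with resources.as_file(ref) as path:
        return TranslationTable.from_csv(path)


@dataclass(frozen=True)
class AntigenTemplate:
    """Scaffold template: triad positions on a glycine-spacer backbone.

    Positions are 1-based from the N terminus.  The default renders the
    nonamer pattern ``GGXGXGGXG`` with the triad at P3, P5, P8.
    """

    length: int = 9
    triad_positions: tuple[int, ...] = (3, 5, 8)
    spacer: str = "G"

    def __post_init__(self) -> None:
        pos = self.triad_positions
        if len(set(pos)) != len(pos) or list(pos) != sorted(pos):
            raise ValueError(f"triad positions must be distinct and increasing: {pos}")
        if pos and (pos[0] < 1 or pos[-1] > self.length):
            raise ValueError(f"triad positions {pos} outside [1, {self.length}]")

    def render(self, triad: Sequence[str]) -> str:
        """Fill the triad positions with the given letters, spacers elsewhere."""
        if len(triad) != len(self.triad_positions):
            raise ValueError(
                f"expected {len(self.triad_positions)} triad letters, got {len(triad)}"
            )
        seq = [self.spacer] * self.length
        for p, letter in zip(self.triad_positions, triad):
            seq[p - 1] = letter
        return "".join(seq)


def default_template() -> AntigenTemplate:
    return AntigenTemplate()


def translate_residue(residue: str, table: TranslationTable | None = None) -> str:
    """Map one natural one-letter code to its SCAA class representative."""
    table = table or default_table()
    try:
        return table[residue]
    except KeyError:
        raise ValueError(f"unknown amino-acid code {residue!r}") from None


def translate_triad(
    triad: Sequence[str], table: TranslationTable | None = None
) -> tuple[str, str, str]:
    """Elementwise SCAA translation of a three-residue triad."""
    table = table or default_table()
    if len(triad) != 3:
        raise ValueError(f"a triad has 3 residues, got {len(triad)}")
    out = []
    for i, code in enumerate(triad):
        try:
            out.append(translate_residue(code, table))
        except ValueError as exc:
            raise ValueError(f"triad position {i + 1}: {exc}") from None
    return tuple(out)


def project_to_template(
    sequence: str,
    template: AntigenTemplate | None = None,
    table: TranslationTable | None = None,
) -> str:
    """Project a natural peptide onto the SCAA scaffold.

    Triad positions are translated into the reduced alphabet; every other
    position becomes the template spacer (glycine), mimicking the removal
    of MHC-anchoring sidechains.
    """
    template = template or default_template()
    table = table or default_table()
    if len(sequence) != template.length:
        raise ValueError(
            f"sequence length {len(sequence)} does not match template length {template.length}"
        )
    triad = [sequence[p - 1] for p in template.triad_positions]
    return template.render(translate_triad(triad, table) if len(triad) == 3
                           else [translate_residue(c, table) for c in triad])


def unique_translated_set(
    sequences: Iterable[str],
    template: AntigenTemplate | None = None,
    table: TranslationTable | None = None,
) -> list[str]:
    """Deduplicated, sorted SCAA projections of a collection of sequences.

    Distinct natural antigens frequently collapse onto the same model
    peptide; the size of the returned set measures that degeneracy.
    """
    template = template or default_template()
    table = table or default_table()
    return sorted({project_to_template(s, template, table) for s in sequences})


def expand_to_natural(
    scaa_letter: str, table: TranslationTable | None = None
) -> frozenset[str]:
    """Inverse image of one SCAA letter: the natural residues in its class."""
    table = table or default_table()
    if scaa_letter not in SCAA_LETTERS:
        raise ValueError(f"not an SCAA letter: {scaa_letter!r}")
    return frozenset(k for k, v in table.mapping.items() if v == scaa_letter)
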