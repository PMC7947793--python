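"""Combinatorial enumeration of SCAA triad libraries.

A full SCAA library places each of the six class representatives at the
three TCR-facing positions, 6³ = 216 peptides, against 20³ = 8,000 for
the natural alphabet.  Positional exclusions derived from the energy
analysis shrink the library further (e.g. dropping one class at two
positions leaves 6 × 5 × 5 = 150).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alphabet import SCAA_LETTERS, AntigenTemplate, default_template

__all__ = ["LibrarySpec", "enumerate_library", "library_size", "reduction_factor"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibrarySpec:
    """Per-position alphabets and exclusions over an antigen template.

    ``alphabet`` and ``exclusions`` are keyed by triad position number
    (e.g. 3, 5, 8); positions absent from ``alphabet`` use the full
    SCAA, positions absent from ``exclusions`` exclude nothing.
    """

    template: AntigenTemplate = field(default_factory=default_template)
    alphabet: Mapping[int, frozenset[str]] = field(default_factory=dict)
    exclusions: Mapping[int, frozenset[str]] = field(default_factory=dict)

    def effective_alphabets(self) -> list[tuple[str, ...]]:
        """Sorted effective alphabet per triad position."""
        out = []
        for pos in self.template.triad_positions:
            letters = frozenset(self.alphabet.get(pos, SCAA_LETTERS))
            letters = letters - frozenset(self.exclusions.get(pos, frozenset()))
            out.append(tuple(sorted(letters)))
        return out


def enumerate_library(spec: LibrarySpec | None = None) -> list[tuple[tuple[str, ...], str]]:
    """All (triad, sequence) pairs in lexicographic triad order.

    The product of the per-position effective alphabets; an empty
    effective alphabet at any position yields an empty library (logged
    as a warning).
    """
    spec = spec or LibrarySpec()
    alphabets = spec.effective_alphabets()
    for pos, letters in zip(spec.template.triad_positions, alphabets):
        if not letters:
            logger.warning("empty effective alphabet at position P%d; empty library", pos)
            return []
    triads = [()]
    for letters in alphabets:
        triads = [t + (x,) for t in triads for x in letters]
    return [(t, spec.template.render(t)) for t in triads]


def library_size(position_alphabet_sizes: Sequence[int]) -> int:
    """Number of combinations: the product of per-position alphabet sizes."""
    sizes = list(position_alphabet_sizes)
    if any(s < 0 for s in sizes):
        raise ValueError(f"negative alphabet size in {sizes}")
    return math.prod(sizes)


def reduction_factor(full_size: float, reduced_size: float) -> float:
    """How many times smaller the reduced library is than the full one."""
    if reduced_size <= 0:
        raise ValueError("reduced library size must be positive")
    return full_size / reduced_size
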