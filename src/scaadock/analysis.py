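"""Ensemble statistics: per-peptide records, the ±σ best-binder window,
positional residual-energy heatmaps and library-reduction proposals.

Each peptide is summarized by the mean interaction energy E_i and mean
contact count C_i over its full pose ensemble (no pose filtering).  The
best-binder window keeps peptides whose (E_i, C_i) fall within one σ of
the library's central values in both dimensions, where σ is by default
the spread (standard deviation) of the per-peptide means across the
library; the standard error of that mean is available as an alternative
σ mode.  Positional heatmaps average E_i per SCAA class and triad
position, and the reduction rule proposes excluding each position's
unique energy maximum — maxima only, since an apparent minimum may
simply reflect force-field bias rather than a true preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    AntigenTemplate,
    TranslationTable,
    default_table,
    default_template,
    translate_triad,
)
from .docking import PoseSet

__all__ = [
    "PeptideRecord",
    "BinderWindow",
    "HeatmapMatrix",
    "aggregate_poses",
    "select_best_binders",
    "flag_reference",
    "positional_heatmap",
    "propose_exclusions",
    "records_to_dataframe",
]

SCAA_ORDER = ("D", "H", "Q", "S", "V", "Y")


@dataclass
class PeptideRecord:
    """Pose-ensemble summary of one library peptide."""

    triad: tuple[str, ...]
    sequence: str
    e_mean: float
    e_sd: float
    e_sem: float
    c_mean: float
    c_sd: float
    n_poses: int
    rmsd_mean: float | None = None
    rmsd_best: float | None = None
    in_window: bool | None = None
    is_reference: bool = False


@dataclass(frozen=True)
class BinderWindow:
    """The ±σ core of the energy–contact map."""

    e_center: float
    e_sigma: float
    c_center: float
    c_sigma: float
    member_ids: tuple[str, ...]
    sigma_mode: str = "sd"

    def contains(self, e: float, c: float) -> bool:
        return (
            abs(e - self.e_center) <= self.e_sigma
            and abs(c - self.c_center) <= self.c_sigma
        )


@dataclass(frozen=True)
class HeatmapMatrix:
    """Mean E_i per SCAA class (rows) and triad position (columns)."""

    mean_energy: pd.DataFrame  # 6 classes x positions, NaN = no occupancy
    counts: pd.DataFrame


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def aggregate_poses(pose_set: PoseSet, triad: Sequence[str] | None = None) -> PeptideRecord:
    """Collapse a pose ensemble into means/SDs/SEMs of E, contacts, RMSD."""
    if len(pose_set) == 0:
        raise ValueError("cannot aggregate an empty pose set")
    triad = tuple(triad) if triad is not None else tuple(pose_set.triad or ())
    e = pose_set.energies()
    c = pose_set.contact_counts().astype(float)
    r = pose_set.rmsds()
    n = len(pose_set)
    return PeptideRecord(
        triad=triad,
        sequence=pose_set.ligand_sequence,
        e_mean=float(e.mean()),
        e_sd=_sd(e),
        e_sem=_sd(e) / np.sqrt(n),
        c_mean=float(c.mean()),
        c_sd=_sd(c),
        n_poses=n,
        rmsd_mean=float(r.mean()) if r is not None else None,
        rmsd_best=float(r.min()) if r is not None else None,
    )


def select_best_binders(
    records: Sequence[PeptideRecord], sigma_mode: str = "sd"
) -> BinderWindow:
    """Select the ±σ window around the library's central (E_i, C_i).

    Centers are the unweighted means of the per-peptide means.  With
    ``sigma_mode="sd"`` (default) σ is the across-library sample SD of
    those means; ``"sem"`` divides it by √(number of peptides).  The
    window boundary is closed; membership is recorded on each record.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to define a window")
    if sigma_mode not in ("sd", "sem"):
        raise ValueError(f"unknown sigma mode {sigma_mode!r}")
    e = np.array([r.e_mean for r in records])
    c = np.array([r.c_mean for r in records])
    e_sigma, c_sigma = _sd(e), _sd(c)
    if sigma_mode == "sem":
        e_sigma /= np.sqrt(len(records))
        c_sigma /= np.sqrt(len(records))
    window = BinderWindow(
        e_center=float(e.mean()),
        e_sigma=e_sigma,
        c_center=float(c.mean()),
        c_sigma=c_sigma,
        member_ids=tuple(
            r.sequence
            for r in records
            if abs(r.e_mean - e.mean()) <= e_sigma and abs(r.c_mean - c.mean()) <= c_sigma
        ),
        sigma_mode=sigma_mode,
    )
    members = set(window.member_ids)
    for r in records:
        r.in_window = r.sequence in members
    return window


def flag_reference(
    records: Sequence[PeptideRecord],
    reference_triad: Sequence[str],
    table: TranslationTable | None = None,
) -> PeptideRecord:
    """Mark the record carrying the SCAA translation of a natural triad.

    Returns the flagged record; its ``in_window`` field (if already set
    by :func:`select_best_binders`) tells whether the translated antigen
    falls among the best binders.
    """
    translated = translate_triad(reference_triad, table or default_table())
    for r in records:
        if tuple(r.triad) == translated:
            r.is_reference = True
            return r
    raise ValueError(
        f"translated triad {''.join(translated)} (from {''.join(reference_triad)}) "
        "not present in the record set"
    )


def positional_heatmap(
    records: Sequence[PeptideRecord],
    subset: Sequence[PeptideRecord] | None = None,
    template: AntigenTemplate | None = None,
) -> HeatmapMatrix:
    """Mean E_i per (SCAA class, triad position) over a record subset.

    Default subset: the best-binder window members when membership has
    been computed, otherwise all records.  Cells with no contributing
    record are NaN, never zero.
    """
    template = template or default_template()
    if subset is None:
        flagged = [r for r in records if r.in_window]
        subset = flagged if any(r.in_window is not None for r in records) else list(records)
    positions = [f"P{p}" for p in template.triad_positions]
    energy = pd.DataFrame(np.nan, index=list(SCAA_ORDER), columns=positions)
    counts = pd.DataFrame(0, index=list(SCAA_ORDER), columns=positions)
    sums = pd.DataFrame(0.0, index=list(SCAA_ORDER), columns=positions)
    for r in subset:
        for slot, pos in enumerate(positions):
            letter = r.triad[slot]
            sums.loc[letter, pos] += r.e_mean
            counts.loc[letter, pos] += 1
    mask = counts > 0
    energy[mask] = sums[mask] / counts[mask]
    return HeatmapMatrix(mean_energy=energy, counts=counts)


def propose_exclusions(
    heatmap: HeatmapMatrix, policy: str = "positional-max"
) -> dict[int, frozenset[str]]:
    """Advisory library reduction: drop each position's unique energy maximum.

    Ties propose nothing (conservative), and positional minima are never
    excluded.  Returns a per-position mapping suitable for
    :class:`scaadock.library.LibrarySpec` ``exclusions``.
    """
    if policy != "positional-max":
        raise ValueError(f"unknown exclusion policy {policy!r}")
    out: dict[int, frozenset[str]] = {}
    for col in heatmap.mean_energy.columns:
        column = heatmap.mean_energy[col].dropna()
        if len(column) < 2 or column.nunique() < 2:
            continue
        vmax = column.max()
        argmax = column[column == vmax]
        if len(argmax) != 1:
            continue  # tied maxima: exclude nothing
        out[int(str(col).lstrip("P"))] = frozenset(argmax.index)
    return out


def records_to_dataframe(records: Sequence[PeptideRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "peptide_id": i,
                "triad": "".join(r.triad),
                "sequence": r.sequence,
                "E_mean": r.e_mean,
                "E_sd": r.e_sd,
                "E_sem": r.e_sem,
                "C_mean": r.c_mean,
                "C_sd": r.c_sd,
                "rmsd_mean": r.rmsd_mean,
                "rmsd_best": r.rmsd_best,
                "n_poses": r.n_poses,
                "in_window": r.in_window,
                "is_translated_reference": r.is_reference,
            }
        )
    return pd.DataFrame(rows)
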