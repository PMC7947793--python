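"""Pose descriptors: intermolecular contact counts and RMSD measures."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ContactSpec", "compute_contacts", "kabsch_rmsd", "ligand_rmsd"]


@dataclass(frozen=True)
class ContactSpec:
    """Contact definition: distance cutoff over heavy atoms (Å)."""

    cutoff: float = 6.0
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


def compute_contacts(
    receptor_coords: np.ndarray,
    ligand_coords: np.ndarray,
    spec: ContactSpec | None = None,
) -> int:
    """Number of intermolecular atom pairs closer than the cutoff.

    Symmetric in its two coordinate arguments; strictly-less-than
    comparison.  Callers are expected to pass heavy-atom coordinates
    (structures in this package never carry hydrogens).
    """
    spec = spec or ContactSpec()
    a = np.asarray(receptor_coords, dtype=float).reshape(-1, 3)
    b = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        warnings.warn("empty coordinate set: contact count is 0", stacklevel=2)
        return 0
    return int(np.count_nonzero(cdist(a, b) < spec.cutoff))


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after least-squares superposition (proper rotations only).

    Centers both point sets, finds the optimal rotation by SVD with the
    determinant sign corrected to exclude reflections, and returns the
    residual RMSD in Å.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(ac.T @ bc)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.array([1.0, 1.0, sign])
    rot = (u * d) @ vt
    diff = ac @ rot - bc
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


def ligand_rmsd(pose_coords: np.ndarray, reference_coords: np.ndarray) -> float:
    """Direct (no-refit) RMSD between two poses in the same receptor frame."""
    a = np.asarray(pose_coords, dtype=float)
    b = np.asarray(reference_coords, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
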