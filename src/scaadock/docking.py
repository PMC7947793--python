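"""Restrained rigid-body docking of a peptide onto a rigid receptor.

Both partners are fully rigid.  Poses are drawn by uniform random
rotation (quaternion method) plus a translation that places the
peptide's restraint-anchor atoms near the annotated CDR3 loop centers,
then refined by Metropolis Monte Carlo over rigid-body perturbations
with geometric cooling.  Scoring is a deliberately simple intermolecular
force field — 12-6 Lennard-Jones with per-element parameters, Coulomb
electrostatics with a distance-dependent dielectric ε(r) = 4r, and the
flat-bottom AIR penalty — so only relative and statistical behaviour of
the resulting energies is meaningful, not absolute binding affinities.
Units are kcal/mol and Å throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .metrics import ContactSpec, compute_contacts, ligand_rmsd
from .restraints import AmbiguousRestraint, restraint_energy
from .structure import Structure

__all__ = [
    "RigidTransform",
    "ScoringParams",
    "MCSchedule",
    "Pose",
    "PoseSet",
    "EnergyModel",
    "annotate_charges",
    "score_pose",
    "sample_initial_poses",
    "refine_pose",
    "dock_peptide",
]

COULOMB = 332.0637  # kcal mol^-1 Å e^-2

#: Per-element Lennard-Jones parameters: (well depth kcal/mol, rmin/2 Å).
LJ_PARAMS: Mapping[str, tuple[float, float]] = {
    "C": (0.10, 1.95),
    "N": (0.16, 1.85),
    "O": (0.17, 1.75),
    "S": (0.35, 2.00),
}

# Coarse heavy-atom partial charges (e).  Backbone amide dipole with the
# amide/alpha hydrogens lumped onto their heavy atom; sidechain formal
# charges split over the terminal polar atoms; small dipoles on hydroxyl
# and amide groups.  Anything unlisted is neutral.
_BACKBONE_CHARGES = {"N": -0.16, "CA": 0.16, "C": 0.51, "O": -0.51}
_SIDECHAIN_CHARGES: Mapping[str, Mapping[str, float]] = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": 1.0},
    "ARG": {"NH1": 0.5, "NH2": 0.5},
    "HIS": {"ND1": 0.5, "NE2": 0.5},  # imidazolium(+1)
    "SER": {"OG": -0.4, "CB": 0.4},
    "THR": {"OG1": -0.4, "CB": 0.4},
    "TYR": {"OH": -0.4, "CZ": 0.4},
    "ASN": {"OD1": -0.55, "CG": 0.55},
    "GLN": {"OE1": -0.55, "CD": 0.55},
}


def annotate_charges(structure: Structure) -> Structure:
    """Assign the built-in coarse partial charges in place; returns input."""
    for res in structure.residues:
        side = _SIDECHAIN_CHARGES.get(res.name, {})
        for atom in res.atoms:
            if atom.name in _BACKBONE_CHARGES:
                atom.charge = _BACKBONE_CHARGES[atom.name]
            else:
                atom.charge = side.get(atom.name, 0.0)
    return structure


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x' = R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-10) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper and orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class ScoringParams:
    """Force-field knobs for the simplified intermolecular score."""

    lj_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LJ_PARAMS)
    )
    dielectric_model: str = "distance-dependent"  # or "constant"
    dielectric: float = 4.0
    cutoff: float = 12.0  # Å, no switching function
    w_vdw: float = 1.0
    w_elec: float = 1.0
    w_air: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if min(self.w_vdw, self.w_elec, self.w_air) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class MCSchedule:
    """Metropolis Monte Carlo schedule with geometric cooling."""

    steps: int = 600
    rot_step_deg: float = 2.0
    trans_step: float = 0.3  # Å
    t_start: float = 4.0  # in energy units (kcal/mol)
    t_end: float = 0.2
    #: fraction of MC steps proposing large jumps (step sizes scaled by
    #: ``large_move_scale``) so walks can hop between nearby basins
    large_move_prob: float = 0.15
    large_move_scale: float = 6.0
    #: clash relief before MC: translate away from receptor atoms closer
    #: than this overlap distance, then descend E by translation only
    clash_overlap: float = 2.6  # Å
    clash_max_iter: int = 80
    #: deterministic rigid-body polish after MC (Nelder-Mead evaluations)
    polish_maxiter: int = 800
    #: basin-hopping rounds after the walk: perturb the best pose and
    #: re-polish, keeping improvements; drives each pose into the deeper
    #: attractors of its neighbourhood
    hops: int = 3
    hop_rot_deg: float = 20.0
    hop_trans: float = 2.0  # Å
    hop_polish_maxiter: int = 300

    @classmethod
    def thorough(cls) -> "MCSchedule":
        """Heavy basin-hopping schedule for recovery experiments.

        Enough hop rounds that each pose converges to the floor of its
        orientation class rather than the first local minimum it meets;
        roughly five times the cost of the default schedule.
        """
        return cls(hops=20, hop_rot_deg=30.0, hop_trans=3.0, hop_polish_maxiter=200)


@dataclass
class Pose:
    transform: RigidTransform
    e_vdw: float
    e_elec: float
    e_air: float
    e_total: float
    contacts: int = 0
    rmsd_to_reference: float | None = None


@dataclass
class PoseSet:
    poses: list[Pose]
    ligand_sequence: str = ""
    triad: tuple[str, ...] | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.poses)

    def energies(self) -> np.ndarray:
        return np.array([p.e_total for p in self.poses])

    def contact_counts(self) -> np.ndarray:
        return np.array([p.contacts for p in self.poses])

    def rmsds(self) -> np.ndarray | None:
        vals = [p.rmsd_to_reference for p in self.poses]
        return None if any(v is None for v in vals) else np.array(vals)


class EnergyModel:
    """Precompiled pair parameters for fast rescoring of one complex.

    Receptor coordinates are fixed; every evaluation takes transformed
    ligand coordinates.  Pairwise LJ/Coulomb parameters and the AIR atom
    indices are resolved once at construction.
    """

    def __init__(
        self,
        receptor: Structure,
        ligand: Structure,
        restraints: Sequence[AmbiguousRestraint],
        params: ScoringParams | None = None,
    ):
        self.params = params or ScoringParams()
        self.receptor = receptor
        self.ligand = ligand
        self.restraints = list(restraints)
        self.rec_coords = receptor.coords()
        self.lig_coords0 = ligand.coords()

        def _annot(structure: Structure, role: str):
            eps, rmin, q = [], [], []
            for res in structure.residues:
                for atom in res.atoms:
                    if atom.charge is None:
                        raise ValueError(
                            f"{role} atom {res.chain}/{res.resseq}/{atom.name} "
                            "has no partial charge; run annotate_charges first"
                        )
                    try:
                        e, r = self.params.lj_params[atom.element]
                    except KeyError:
                        raise ValueError(
                            f"{role} atom {res.chain}/{res.resseq}/{atom.name}: "
                            f"no LJ parameters for element {atom.element!r}"
                        ) from None
                    eps.append(e)
                    rmin.append(r)
                    q.append(atom.charge)
            return np.array(eps), np.array(rmin), np.array(q)

        re_, rr, rq = _annot(receptor, "receptor")
        le, lr, lq = _annot(ligand, "ligand")
        self._eps = np.sqrt(re_[:, None] * le[None, :])
        self._rmin = rr[:, None] + lr[None, :]
        self._qq = COULOMB * rq[:, None] * lq[None, :]

        # restraint index arrays: ligand flat indices + fixed receptor coords
        self._air = []
        for r in self.restraints:
            lig_idx = np.array(
                [ligand.atom_index(ls.chain, ls.resseq, ls.name) for ls, _ in r.pairs]
            )
            rec_xyz = np.vstack([rs.resolve(receptor) for _, rs in r.pairs])
            self._air.append((r, lig_idx, rec_xyz))

    def energy_terms(self, lig_coords: np.ndarray) -> tuple[float, float, float]:
        """(E_vdw, E_elec, E_air) for ligand coordinates in the receptor frame."""
        p = self.params
        d = cdist(self.rec_coords, lig_coords)
        mask = d < p.cutoff
        dm = d[mask]
        x6 = (self._rmin[mask] / dm) ** 6
        e_vdw = float(np.sum(self._eps[mask] * (x6 * x6 - 2.0 * x6)))
        qq = self._qq[mask]
        if p.dielectric_model == "distance-dependent":
            e_elec = float(np.sum(qq / (p.dielectric * dm * dm)))
        else:
            e_elec = float(np.sum(qq / (p.dielectric * dm)))
        e_air = 0.0
        for r, lig_idx, rec_xyz in self._air:
            dd = np.linalg.norm(lig_coords[lig_idx] - rec_xyz, axis=1)
            d_eff = float(np.sum(dd ** -6.0) ** (-1.0 / 6.0))
            e_air += restraint_energy(r, d_eff)
        return e_vdw, e_elec, e_air

    def effective_distances(self, lig_coords: np.ndarray) -> list[float]:
        out = []
        for _, lig_idx, rec_xyz in self._air:
            dd = np.linalg.norm(lig_coords[lig_idx] - rec_xyz, axis=1)
            out.append(float(np.sum(dd ** -6.0) ** (-1.0 / 6.0)))
        return out

    def score_transform(self, transform: RigidTransform) -> Pose:
        coords = transform.apply(self.lig_coords0)
        e_vdw, e_elec, e_air = self.energy_terms(coords)
        p = self.params
        total = p.w_vdw * e_vdw + p.w_elec * e_elec + p.w_air * e_air
        return Pose(transform, e_vdw, e_elec, e_air, total)

    def anchor_centroids(self) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Per-restraint ligand anchor centroids (base frame) and receptor targets."""
        lig_cents = [self.lig_coords0[idx].mean(axis=0) for _, idx, _ in self._air]
        rec_cents = [xyz.mean(axis=0) for _, _, xyz in self._air]
        overall = np.mean(rec_cents, axis=0)
        return overall, lig_cents, rec_cents


def score_pose(
    receptor: Structure,
    ligand: Structure,
    transform: RigidTransform,
    restraints: Sequence[AmbiguousRestraint],
    params: ScoringParams | None = None,
) -> Pose:
    """Score a single pose (convenience wrapper over :class:`EnergyModel`)."""
    return EnergyModel(receptor, ligand, restraints, params).score_transform(transform)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def sample_initial_poses(
    receptor: Structure,
    ligand: Structure,
    restraints: Sequence[AmbiguousRestraint],
    n: int,
    seed: int,
    params: ScoringParams | None = None,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[RigidTransform]:
    """Draw ``n`` restraint-aware starting transforms, reproducibly.

    Each pose combines a uniform random rotation with a translation that
    puts every restraint's ligand-anchor centroid at a randomly chosen
    distance within the flat-bottom band of its receptor target (solved
    by least squares when several restraints compete), so most starting
    poses already satisfy the AIRs.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    model = model or EnergyModel(receptor, ligand, restraints, params)
    rng = rng if rng is not None else np.random.default_rng(seed)
    _, lig_cents, rec_cents = model.anchor_centroids()
    mid = np.mean([(r.lower + r.upper) / 2.0 for r in model.restraints])
    lo, hi = mid - 0.5, mid + 0.5
    out = []
    for _ in range(n):
        rot = _random_rotation(rng)
        rotated = [rot @ c for c in lig_cents]
        targets = rng.uniform(lo, hi, size=len(rec_cents))
        t0 = np.mean(rec_cents, axis=0) - np.mean(rotated, axis=0) \
            + rng.normal(scale=1.0, size=3)

        def resid(t, rotated=rotated, targets=targets):
            return np.array(
                [
                    np.linalg.norm(rc + t - pc) - tgt
                    for rc, pc, tgt in zip(rotated, rec_cents, targets)
                ]
            )

        sol = least_squares(resid, t0, method="trf", max_nfev=200)
        if not np.all(np.isfinite(sol.x)):
            raise RuntimeError("infeasible restraint geometry: no initial placement found")
        out.append(RigidTransform(rot, sol.x))
    return out


def refine_pose(
    receptor: Structure,
    ligand: Structure,
    transform: RigidTransform,
    restraints: Sequence[AmbiguousRestraint],
    params: ScoringParams | None = None,
    schedule: MCSchedule | None = None,
    seed: int = 0,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
) -> Pose:
    """Rigid-body refinement; returns the best (lowest E_total) pose visited.

    Three stages, all seeded and deterministic: a translation-only
    steepest-descent that relieves steric clashes of the random start, a
    Metropolis Monte Carlo walk with geometric cooling (rotations applied
    about the ligand centroid so rotation and translation moves stay
    decoupled), and a derivative-free local polish of the best pose.  A
    zero-step schedule returns the scored input pose unchanged.
    """
    model = model or EnergyModel(receptor, ligand, restraints, params)
    schedule = schedule or MCSchedule()
    rng = rng if rng is not None else np.random.default_rng(seed)

    best = model.score_transform(transform)
    if schedule.steps <= 0:
        return best

    def relieve(pose: Pose) -> Pose:
        # geometric overlap relief — translate away from receptor atoms
        # that interpenetrate the ligand (raw LJ gradients are useless at
        # such separations)
        current = pose
        for _ in range(schedule.clash_max_iter):
            tr = current.transform
            coords = tr.apply(model.lig_coords0)
            close = cdist(model.rec_coords, coords) < schedule.clash_overlap
            if not close.any():
                break
            ri, li = np.nonzero(close)
            push = (coords[li] - model.rec_coords[ri]).sum(axis=0)
            norm = np.linalg.norm(push)
            if norm < 1e-9:  # perfectly symmetric overlap: nudge along +z
                push, norm = np.array([0.0, 0.0, 1.0]), 1.0
            current = model.score_transform(
                RigidTransform(tr.rotation, tr.translation + 0.3 * push / norm)
            )
        return current

    def mc_walk(start: Pose, best: Pose) -> Pose:
        current = start
        temps = np.geomspace(schedule.t_start, schedule.t_end, schedule.steps)
        for temp in temps:
            tr = current.transform
            centroid = tr.apply(model.lig_coords0).mean(axis=0)
            scale = (
                schedule.large_move_scale
                if rng.random() < schedule.large_move_prob
                else 1.0
            )
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.radians(rng.normal(scale=scale * schedule.rot_step_deg))
            d_rot = Rotation.from_rotvec(axis * ang).as_matrix()
            shift = rng.normal(scale=scale * schedule.trans_step, size=3)
            new_rot = d_rot @ tr.rotation
            new_t = d_rot @ (tr.translation - centroid) + centroid + shift
            cand = model.score_transform(RigidTransform(new_rot, new_t))
            delta = cand.e_total - current.e_total
            if delta <= 0 or rng.random() < np.exp(-delta / temp):
                current = cand
                if current.e_total < best.e_total:
                    best = current
        return best

    def objective(x):
        tr = RigidTransform(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])
        return model.score_transform(tr).e_total

    def polish(best: Pose, maxiter: int) -> Pose:
        if maxiter <= 0:
            return best
        rv0 = Rotation.from_matrix(best.transform.rotation).as_rotvec()
        x0 = np.concatenate([rv0, best.transform.translation])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-9})
        polished = model.score_transform(
            RigidTransform(Rotation.from_rotvec(res.x[:3]).as_matrix(), res.x[3:])
        )
        return polished if polished.e_total < best.e_total else best

    # relief -> MC -> polish; restart from the current best if the walk
    # ends wedged at unphysical positive energy
    for _ in range(3):
        start = relieve(best)
        if start.e_total < best.e_total:
            best = start
        best = polish(mc_walk(start, best), schedule.polish_maxiter)
        if best.e_total <= 0.0:
            break

    # basin hopping: jump out of the current minimum and re-polish,
    # keeping only improvements, so poses concentrate in deep attractors
    for _ in range(schedule.hops):
        tr = best.transform
        centroid = tr.apply(model.lig_coords0).mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.radians(rng.normal(scale=schedule.hop_rot_deg))
        d_rot = Rotation.from_rotvec(axis * ang).as_matrix()
        shift = rng.normal(scale=schedule.hop_trans, size=3)
        hopped = model.score_transform(
            RigidTransform(
                d_rot @ tr.rotation,
                d_rot @ (tr.translation - centroid) + centroid + shift,
            )
        )
        hopped = polish(hopped, schedule.hop_polish_maxiter)
        if hopped.e_total < best.e_total:
            best = hopped
    return best


def dock_peptide(
    receptor: Structure,
    ligand: Structure,
    restraints: Sequence[AmbiguousRestraint],
    params: ScoringParams | None = None,
    n_poses: int = 100,
    seed: int = 0,
    schedule: MCSchedule | None = None,
    contact_spec: ContactSpec | None = None,
    reference_ca: np.ndarray | None = None,
) -> PoseSet:
    """Sample, refine and score ``n_poses`` rigid poses of one peptide.

    Every pose is retained (downstream statistics average over the whole
    ensemble); poses are sorted by ascending E_total.  Bit-identical for
    a fixed seed.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    if any(a.charge is None for a in ligand.atoms()):
        ligand = annotate_charges(ligand.copy())
    if any(a.charge is None for a in receptor.atoms()):
        receptor = annotate_charges(receptor.copy())
    model = EnergyModel(receptor, ligand, restraints, params)
    contact_spec = contact_spec or ContactSpec()
    rng = np.random.default_rng(seed)
    starts = sample_initial_poses(
        receptor, ligand, restraints, n_poses, seed, model=model, rng=rng
    )
    poses = []
    lig_ca_idx = [
        ligand.atom_index(r.chain, r.resseq, "CA") for r in ligand.residues
    ]
    for tr in starts:
        pose = refine_pose(
            receptor, ligand, tr, restraints, schedule=schedule, model=model, rng=rng
        )
        coords = pose.transform.apply(model.lig_coords0)
        pose.contacts = compute_contacts(model.rec_coords, coords, contact_spec)
        if reference_ca is not None:
            pose.rmsd_to_reference = ligand_rmsd(coords[lig_ca_idx], reference_ca)
        poses.append(pose)
    poses.sort(key=lambda p: p.e_total)
    return PoseSet(
        poses,
        ligand_sequence=ligand.sequence,
        triad=ligand.meta.get("triad"),
        seed=seed,
    )
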