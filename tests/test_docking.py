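"""Rigid-body docking engine: scoring oracle equality, invariances,
sampling and refinement contracts (fast checks; the full recovery
experiment lives in the acceptance suite)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scaadock.builder import build_library_peptide
from scaadock.docking import (
    COULOMB,
    EnergyModel,
    MCSchedule,
    RigidTransform,
    ScoringParams,
    annotate_charges,
    dock_peptide,
    refine_pose,
    sample_initial_poses,
    score_pose,
)
from scaadock.structure import Atom, Residue, Structure


def brute_force_energy(receptor, ligand, params):
    """Independent double-loop pair sum (no transform)."""
    e_vdw = e_elec = 0.0
    for res_r in receptor.residues:
        for ar in res_r.atoms:
            for res_l in ligand.residues:
                for al in res_l.atoms:
                    d = float(np.linalg.norm(ar.coord - al.coord))
                    if d >= params.cutoff:
                        continue
                    eps = np.sqrt(
                        params.lj_params[ar.element][0] * params.lj_params[al.element][0]
                    )
                    rmin = params.lj_params[ar.element][1] + params.lj_params[al.element][1]
                    x6 = (rmin / d) ** 6
                    e_vdw += eps * (x6 * x6 - 2 * x6)
                    e_elec += COULOMB * ar.charge * al.charge / (4.0 * d * d)
    return e_vdw, e_elec


class TestScoring:
    def test_matches_brute_force_pair_sum(self, planted):
        params = ScoringParams()
        moved = planted.ligand.transformed(
            planted.planted_transform.rotation, planted.planted_transform.translation
        )
        model = EnergyModel(planted.receptor, moved, planted.restraints, params)
        e_vdw, e_elec, _ = model.energy_terms(moved.coords())
        bf_vdw, bf_elec = brute_force_energy(planted.receptor, moved, params)
        assert e_vdw == pytest.approx(bf_vdw, abs=1e-9)
        assert e_elec == pytest.approx(bf_elec, abs=1e-9)

    def test_far_ligand_has_only_air_energy(self, planted):
        far = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        pose = score_pose(planted.receptor, planted.ligand, far, planted.restraints)
        assert pose.e_vdw == 0.0
        assert pose.e_elec == 0.0
        assert pose.e_air > 0.0
        assert pose.e_total == pytest.approx(pose.e_air)

    def test_two_neutral_atoms_at_lj_minimum(self):
        params = ScoringParams()
        eps, rmin_half = params.lj_params["C"]
        rec = Structure([Residue("GLY", 1, "R", [Atom("CA", "C", [0, 0, 0], 0.0)])])
        lig = Structure([Residue("GLY", 1, "A", [Atom("CA", "C", [2 * rmin_half, 0, 0], 0.0)])])
        model = EnergyModel(rec, lig, [], params)
        e_vdw, e_elec, _ = model.energy_terms(lig.coords())
        assert e_vdw == pytest.approx(-eps, abs=1e-12)
        assert e_elec == 0.0

    def test_invariant_under_common_rigid_motion(self, planted):
        params = ScoringParams()
        moved_lig = planted.ligand.transformed(
            planted.planted_transform.rotation, planted.planted_transform.translation
        )
        model = EnergyModel(planted.receptor, moved_lig, planted.restraints, params)
        base = model.energy_terms(moved_lig.coords())

        rot = Rotation.from_euler("xyz", [0.3, -0.7, 1.1]).as_matrix()
        shift = np.array([3.0, -5.0, 2.0])
        rec2 = planted.receptor.transformed(rot, shift)
        lig2 = moved_lig.transformed(rot, shift)
        model2 = EnergyModel(rec2, lig2, planted.restraints, params)
        both = model2.energy_terms(lig2.coords())
        assert np.allclose(base, both, atol=1e-9)

    def test_missing_charge_is_named(self, planted):
        lig = planted.ligand.copy()
        lig.residues[2].atoms[0].charge = None
        with pytest.raises(ValueError, match="no partial charge"):
            EnergyModel(planted.receptor, lig, planted.restraints)

    def test_zero_air_inside_flat_bottom(self, planted):
        pose = score_pose(
            planted.receptor, planted.ligand, planted.planted_transform,
            planted.restraints,
        )
        assert pose.e_air == 0.0

    def test_total_is_weighted_sum(self, planted):
        params = ScoringParams(w_vdw=0.5, w_elec=2.0, w_air=3.0)
        pose = score_pose(
            planted.receptor, planted.ligand, planted.planted_transform,
            planted.restraints, params,
        )
        assert pose.e_total == pytest.approx(
            0.5 * pose.e_vdw + 2.0 * pose.e_elec + 3.0 * pose.e_air
        )


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        reflection = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflection, np.zeros(3))

    def test_composition_matches_sequential_application(self):
        rng = np.random.default_rng(0)
        t1 = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        t2 = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        assert np.allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)))


class TestSampling:
    def test_zero_poses_gives_empty_list(self, planted):
        assert sample_initial_poses(
            planted.receptor, planted.ligand, planted.restraints, 0, seed=1
        ) == []

    def test_same_seed_is_identical(self, planted):
        a = sample_initial_poses(
            planted.receptor, planted.ligand, planted.restraints, 5, seed=7
        )
        b = sample_initial_poses(
            planted.receptor, planted.ligand, planted.restraints, 5, seed=7
        )
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.rotation, tb.rotation)
            assert np.array_equal(ta.translation, tb.translation)

    def test_most_starts_satisfy_restraints(self, planted):
        model = EnergyModel(planted.receptor, planted.ligand, planted.restraints)
        starts = sample_initial_poses(
            planted.receptor, planted.ligand, planted.restraints, 200, seed=11,
            model=model,
        )
        frac = np.mean([model.score_transform(t).e_air == 0.0 for t in starts])
        assert frac >= 0.5


class TestRefine:
    def test_zero_step_schedule_returns_scored_input(self, planted):
        sched = MCSchedule(steps=0)
        pose = refine_pose(
            planted.receptor, planted.ligand, planted.planted_transform,
            planted.restraints, schedule=sched, seed=0,
        )
        assert np.array_equal(
            pose.transform.rotation, planted.planted_transform.rotation
        )
        assert pose.e_total == pytest.approx(planted.planted_pose.e_total)

    def test_never_worse_than_start(self, planted):
        sched = MCSchedule(steps=50, polish_maxiter=50, hops=1, hop_polish_maxiter=30)
        pose = refine_pose(
            planted.receptor, planted.ligand, planted.planted_transform,
            planted.restraints, schedule=sched, seed=3,
        )
        assert pose.e_total <= planted.planted_pose.e_total + 1e-9


class TestDockPeptide:
    def test_single_pose_set(self, planted):
        sched = MCSchedule(steps=20, polish_maxiter=30, hops=0)
        ps = dock_peptide(
            planted.receptor, planted.ligand, planted.restraints,
            n_poses=1, seed=5, schedule=sched,
        )
        assert len(ps) == 1
        assert ps.poses[0].contacts > 0

    def test_same_seed_bit_identical(self, planted):
        sched = MCSchedule(steps=30, polish_maxiter=30, hops=0)
        a = dock_peptide(planted.receptor, planted.ligand, planted.restraints,
                         n_poses=3, seed=9, schedule=sched)
        b = dock_peptide(planted.receptor, planted.ligand, planted.restraints,
                         n_poses=3, seed=9, schedule=sched)
        assert [p.e_total for p in a.poses] == [p.e_total for p in b.poses]
        for pa, pb in zip(a.poses, b.poses):
            assert np.array_equal(pa.transform.translation, pb.transform.translation)

    def test_poses_sorted_by_energy(self, planted):
        sched = MCSchedule(steps=30, polish_maxiter=30, hops=0)
        ps = dock_peptide(planted.receptor, planted.ligand, planted.restraints,
                          n_poses=5, seed=2, schedule=sched)
        e = [p.e_total for p in ps.poses]
        assert e == sorted(e)

    def test_auto_annotates_charges(self, planted):
        ligand = build_library_peptide(("V", "V", "V"))  # no charges yet
        sched = MCSchedule(steps=10, polish_maxiter=10, hops=0)
        ps = dock_peptide(planted.receptor, ligand, planted.restraints,
                          n_poses=1, seed=1, schedule=sched)
        assert len(ps) == 1

    def test_rejects_zero_poses(self, planted):
        with pytest.raises(ValueError):
            dock_peptide(planted.receptor, planted.ligand, planted.restraints,
                         n_poses=0, seed=1)
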