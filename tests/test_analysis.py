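"""Ensemble aggregation, the ±σ best-binder window, positional heatmaps
and the exclusion-based library reduction."""

import numpy as np
import pytest

from scaadock.analysis import (
    PeptideRecord,
    aggregate_poses,
    flag_reference,
    positional_heatmap,
    propose_exclusions,
    records_to_dataframe,
    select_best_binders,
)
from scaadock.docking import Pose, PoseSet, RigidTransform
from scaadock.fixtures import EffectSpec, make_gaussian_records, make_synthetic_records
from scaadock.library import LibrarySpec, enumerate_library


def _pose_set(energies, contacts=None, rmsds=None):
    contacts = contacts or [0] * len(energies)
    poses = [
        Pose(RigidTransform.identity(), e, 0.0, 0.0, e, c,
             None if rmsds is None else rmsds[i])
        for i, (e, c) in enumerate(zip(energies, contacts))
    ]
    return PoseSet(poses, ligand_sequence="GGVGVGGVG", triad=("V", "V", "V"))


class TestAggregate:
    def test_mean_sd_sem_arithmetic(self):
        rec = aggregate_poses(_pose_set([-10.0, -12.0, -14.0]))
        assert rec.e_mean == pytest.approx(-12.0)
        assert rec.e_sd == pytest.approx(2.0)
        assert rec.e_sem == pytest.approx(2.0 / np.sqrt(3))

    def test_single_pose_sd_convention(self):
        rec = aggregate_poses(_pose_set([-10.0]))
        assert rec.e_sd == 0.0 and rec.e_sem == 0.0

    def test_matches_numpy_oracle_on_random_ensemble(self):
        rng = np.random.default_rng(0)
        e = rng.normal(-15, 3, size=100)
        c = rng.integers(100, 400, size=100)
        r = rng.uniform(0, 10, size=100)
        rec = aggregate_poses(_pose_set(list(e), list(c), list(r)))
        assert rec.e_mean == pytest.approx(e.mean(), abs=1e-12)
        assert rec.e_sd == pytest.approx(e.std(ddof=1), abs=1e-12)
        assert rec.c_mean == pytest.approx(c.mean(), abs=1e-12)
        assert rec.rmsd_mean == pytest.approx(r.mean(), abs=1e-12)
        assert rec.rmsd_best == pytest.approx(r.min(), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            aggregate_poses(PoseSet([]))


class TestBinderWindow:
    def test_identical_records_are_all_members(self):
        records = make_synthetic_records(10, EffectSpec(offsets={}, noise_sd=0.0,
                                                        c_noise_sd=0.0))
        window = select_best_binders(records)
        assert len(window.member_ids) == 10
        assert all(r.in_window for r in records)

    def test_member_fraction_on_independent_normals(self):
        # Monte-Carlo oracle: P(|Z| <= 1)^2 = 0.683^2 = 0.466
        records = make_gaussian_records(10_000, seed=123)
        window = select_best_binders(records)
        frac = len(window.member_ids) / len(records)
        assert frac == pytest.approx(0.466, abs=0.02)

    def test_boundary_is_closed(self):
        records = make_gaussian_records(100, seed=5)
        window = select_best_binders(records)
        e = window.e_center + window.e_sigma
        assert window.contains(e, window.c_center)

    def test_membership_matches_double_inequality(self):
        records = make_gaussian_records(500, seed=9)
        window = select_best_binders(records)
        for r in records:
            expected = (
                abs(r.e_mean - window.e_center) <= window.e_sigma
                and abs(r.c_mean - window.c_center) <= window.c_sigma
            )
            assert r.in_window == expected

    def test_sem_mode_shrinks_sigma(self):
        records = make_gaussian_records(400, seed=2)
        sd = select_best_binders(records, sigma_mode="sd")
        sem = select_best_binders(records, sigma_mode="sem")
        assert sem.e_sigma == pytest.approx(sd.e_sigma / 20.0)

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            select_best_binders(make_gaussian_records(1))


class TestFlagReference:
    def test_flags_translated_triad(self):
        records = make_synthetic_records(216)
        rec = flag_reference(records, ("N", "V", "R"))
        assert rec.triad == ("Q", "V", "H")
        assert rec.is_reference

    def test_scaa_reference_flags_itself(self):
        records = make_synthetic_records(216)
        rec = flag_reference(records, ("Y", "V", "D"))
        assert rec.triad == ("Y", "V", "D")

    def test_absent_translation_rejected(self):
        records = make_synthetic_records(2)
        with pytest.raises(ValueError, match="not present"):
            flag_reference(records, ("N", "V", "R"))


class TestHeatmap:
    def test_shape_is_six_by_three(self):
        hm = positional_heatmap(make_synthetic_records(216))
        assert hm.mean_energy.shape == (6, 3)
        assert list(hm.mean_energy.columns) == ["P3", "P5", "P8"]

    def test_occupancy_sums_to_record_count(self):
        records = make_synthetic_records(216)
        hm = positional_heatmap(records)
        assert (hm.counts.sum(axis=0) == 216).all()

    def test_planted_offset_is_global_maximum(self):
        spec = EffectSpec(offsets={("S", 5): 10.0}, noise_sd=0.1)
        hm = positional_heatmap(make_synthetic_records(216, spec))
        assert hm.mean_energy.values.max() == hm.mean_energy.loc["S", "P5"]

    def test_matches_brute_force_groupby(self):
        records = make_synthetic_records(216, EffectSpec(offsets={}, noise_sd=2.0))
        hm = positional_heatmap(records)
        for letter in "DHQSVY":
            vals = [r.e_mean for r in records if r.triad[1] == letter]
            assert hm.mean_energy.loc[letter, "P5"] == pytest.approx(
                np.mean(vals), abs=1e-12
            )

    def test_empty_cell_is_nan_not_zero(self):
        records = make_synthetic_records(216)
        subset = [r for r in records if r.triad[0] != "D"]
        hm = positional_heatmap(records, subset=subset)
        assert np.isnan(hm.mean_energy.loc["D", "P3"])
        assert hm.counts.loc["D", "P3"] == 0

    def test_invariant_to_record_order(self):
        records = make_synthetic_records(216, EffectSpec(offsets={}, noise_sd=1.0))
        hm1 = positional_heatmap(records)
        hm2 = positional_heatmap(list(reversed(records)))
        assert np.allclose(hm1.mean_energy.values, hm2.mean_energy.values)


class TestExclusions:
    def test_unique_maxima_excluded_ties_kept(self):
        spec = EffectSpec(offsets={("S", 5): 10.0, ("D", 8): 10.0}, noise_sd=0.1)
        hm = positional_heatmap(make_synthetic_records(216, spec))
        # P3 has no planted effect: its noise-level maxima are still unique
        # per column, so restrict the check to the planted positions
        proposals = propose_exclusions(hm)
        assert proposals[5] == frozenset("S")
        assert proposals[8] == frozenset("D")

    def test_flat_heatmap_proposes_nothing(self):
        spec = EffectSpec(offsets={}, noise_sd=0.0, c_noise_sd=0.0)
        hm = positional_heatmap(make_synthetic_records(216, spec))
        assert propose_exclusions(hm) == {}

    def test_minimum_is_never_excluded(self):
        spec = EffectSpec(offsets={("Y", 5): -10.0}, noise_sd=0.1)
        hm = positional_heatmap(make_synthetic_records(216, spec))
        proposals = propose_exclusions(hm)
        assert "Y" not in proposals.get(5, frozenset())

    def test_reduction_to_150_end_to_end(self):
        spec = EffectSpec(offsets={("S", 5): 10.0, ("D", 8): 10.0}, noise_sd=0.1)
        records = make_synthetic_records(216, spec)
        select_best_binders(records)
        hm = positional_heatmap(records, subset=records)
        proposals = propose_exclusions(hm)
        reduced = enumerate_library(
            LibrarySpec(exclusions={5: proposals[5], 8: proposals[8]})
        )
        assert len(reduced) == 150


class TestDataFrame:
    def test_columns_and_row_count(self):
        records = make_synthetic_records(10)
        df = records_to_dataframe(records)
        assert len(df) == 10
        for col in ("triad", "sequence", "E_mean", "C_mean", "in_window",
                    "is_translated_reference"):
            assert col in df.columns


class TestPlotting:
    def test_figures_render(self, tmp_path):
        from scaadock.plotting import energy_contact_map, heatmap_figure

        records = make_gaussian_records(50, seed=1)
        window = select_best_binders(records)
        records[0].is_reference = True
        fig = energy_contact_map(records, window)
        fig.savefig(tmp_path / "map.png", dpi=50)
        hm = positional_heatmap(records, subset=records)
        heatmap_figure(hm).savefig(tmp_path / "hm.png", dpi=50)
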