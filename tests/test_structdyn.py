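"""Superposition, RMSF, contacts, H-bond distances and B-factor profiles."""

import numpy as np
import pytest

from ttrstab import (
    StructureModel,
    Trajectory,
    TrajectorySpec,
    bfactor_profile,
    contact_persistence,
    gen_trajectory,
    hbond_distance,
    make_reference_structure,
    region_contact_frequency,
    rmsf_compare,
    rmsf_windowed,
    superpose,
)
from ttrstab.structdyn import (
    ContactRecord,
    _kabsch,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def transformed_copy(model, R, t):
    return StructureModel(
        model.chain, model.resnum, model.resname, model.name, model.element,
        model.xyz @ R.T + t, model.bfactor, model.occupancy,
    )


class TestSuperpose:
    def test_self_superposition_is_zero(self):
        ref = make_reference_structure(10)
        res = superpose(ref, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.n_matched == 10

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        ref = make_reference_structure(15)
        R, t = random_rotation(rng), rng.normal(scale=10.0, size=3)
        res = superpose(transformed_copy(ref, R, t), ref)
        assert res.rmsd < 1e-8
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(2)
        a = make_reference_structure(12)
        # a perturbed copy, so the rmsd is non-trivial
        b = StructureModel(
            a.chain, a.resnum, a.resname, a.name, a.element,
            a.xyz + rng.normal(scale=0.5, size=a.xyz.shape),
            a.bfactor, a.occupancy,
        )
        d_ab = superpose(a, b).rmsd
        d_ba = superpose(b, a).rmsd
        assert d_ab == pytest.approx(d_ba, rel=1e-9)
        R, t = random_rotation(rng), rng.normal(scale=5.0, size=3)
        assert superpose(transformed_copy(a, R, t), b).rmsd == pytest.approx(d_ab, rel=1e-9)

    def test_matches_biopython_superimposer_oracle(self):
        from Bio.PDB.Superimposer import Superimposer
        from Bio.SVDSuperimposer import SVDSuperimposer

        rng = np.random.default_rng(3)
        P = rng.normal(size=(30, 3)) * 5.0
        Q = P + rng.normal(size=(30, 3)) * 0.8
        R, t, rmsd = _kabsch(P, Q)
        sup = SVDSuperimposer()
        sup.set(Q, P)   # SVDSuperimposer fits the second array onto the first
        sup.run()
        assert rmsd == pytest.approx(float(sup.get_rms()), rel=1e-9)
        R_o, t_o = sup.get_rotran()
        np.testing.assert_allclose(P @ R.T + t, P @ R_o + t_o, atol=1e-9)

    def test_unmatched_residues_skipped_and_reported(self):
        a = make_reference_structure(12)
        b = make_reference_structure(10)   # misses residues 11-12
        res = superpose(a, b)
        assert res.n_matched == 10
        assert ("A", 11, "CA") in res.skipped and ("A", 12, "CA") in res.skipped

    def test_too_few_pairs_rejected(self):
        a = make_reference_structure(2)
        with pytest.raises(ValueError, match="at least 3"):
            superpose(a, a)


class TestRMSF:
    def test_static_trajectory_has_zero_rmsf(self):
        ref = make_reference_structure(8)
        spec = TrajectorySpec(n_residues=8, n_frames=20, per_residue_sigma=0.0)
        traj = gen_trajectory(spec, ref)
        prof = rmsf_windowed(traj, window_ns=20 * 4.0 / 1000.0)
        np.testing.assert_allclose(prof.mean, 0.0, atol=1e-12)

    def test_isotropic_gaussian_rmsf_matches_analytic_value(self):
        """sigma = 0.5 A per coordinate -> RMSF = sigma*sqrt(3) ~ 0.866 A."""
        n_frames = 2500
        ref = make_reference_structure(64)
        spec = TrajectorySpec(
            n_residues=64, n_frames=n_frames, per_residue_sigma=0.5, seed=9
        )
        traj = gen_trajectory(spec, ref)
        prof = rmsf_windowed(traj, window_ns=n_frames * 4.0 / 1000.0)
        expected = 0.5 * np.sqrt(3.0)
        assert prof.mean.mean() == pytest.approx(expected, rel=0.03)

    def test_window_average_of_two_regimes(self):
        """Two windows with different sigma: profile = mean of the analytic
        per-window values."""
        ref = make_reference_structure(40)
        frames = []
        for sigma, seed in ((0.3, 1), (0.6, 2)):
            spec = TrajectorySpec(
                n_residues=40, n_frames=1500, per_residue_sigma=sigma, seed=seed
            )
            frames.append(gen_trajectory(spec, ref).xyz)
        traj = Trajectory(ref, np.concatenate(frames), 4.0)
        prof = rmsf_windowed(traj, window_ns=1500 * 4.0 / 1000.0)
        assert prof.per_window.shape[0] == 2
        expected = 0.5 * (0.3 + 0.6) * np.sqrt(3.0)
        assert prof.mean.mean() == pytest.approx(expected, rel=0.04)

    def test_trailing_partial_window_discarded(self):
        ref = make_reference_structure(6)
        spec = TrajectorySpec(n_residues=6, n_frames=25, per_residue_sigma=0.2)
        traj = gen_trajectory(spec, ref)
        prof = rmsf_windowed(traj, window_ns=10 * 4.0 / 1000.0)
        assert prof.per_window.shape[0] == 2   # 25 frames -> 2 windows of 10

    def test_empty_selection_rejected(self):
        ref = make_reference_structure(6)
        spec = TrajectorySpec(n_residues=6, n_frames=10, per_residue_sigma=0.1)
        traj = gen_trajectory(spec, ref)
        with pytest.raises(ValueError, match="matches no atoms"):
            rmsf_windowed(traj, window_ns=10 * 4.0 / 1000.0, selection="XX")


class TestRMSFCompare:
    def _profile(self, sigma, seed=0, n_res=70):
        ref = make_reference_structure(n_res)
        spec = TrajectorySpec(
            n_residues=n_res, n_frames=600, per_residue_sigma=sigma, seed=seed
        )
        traj = gen_trajectory(spec, ref)
        return rmsf_windowed(traj, window_ns=600 * 4.0 / 1000.0)

    def test_identical_profiles_give_zero_delta(self):
        a = self._profile(0.3, seed=4)
        out = rmsf_compare(a, a)
        np.testing.assert_allclose(out["delta"], 0.0, atol=1e-12)

    def test_bc_loop_contrast_detected(self):
        """Doubling sigma in the BC loop (residues 36-40) of the 'mutant'
        raises the BC-region mean difference above the DE region's."""
        n_res = 70
        sig_wt = np.full(n_res, 0.3)
        sig_mut = sig_wt.copy()
        sig_mut[35:40] = 0.6   # residues 36-40, zero-based slice
        a = self._profile(tuple(sig_mut), seed=5, n_res=n_res)
        b = self._profile(tuple(sig_wt), seed=6, n_res=n_res)
        out = rmsf_compare(a, b)
        assert out["regions"]["BC"]["mean_delta"] > 0.2
        assert out["regions"]["BC"]["mean_delta"] > out["regions"]["DE"]["mean_delta"]

    def test_region_outside_range_rejected(self):
        a = self._profile(0.3, seed=7, n_res=20)
        with pytest.raises(ValueError, match="no profiled residues"):
            rmsf_compare(a, a, regions={"BC": (36, 40)})

    def test_mismatched_residues_rejected(self):
        a = self._profile(0.3, seed=8, n_res=20)
        b = self._profile(0.3, seed=8, n_res=21)
        with pytest.raises(ValueError, match="different residues"):
            rmsf_compare(a, b, regions={"X": (1, 20)})


def bruteforce_contacts(traj, cutoff=4.5, min_seq_sep=2):
    """Frame-by-frame all-pairs oracle, straight from the definitions."""
    topo = traj.topology
    sc = topo.sidechain_mask()
    residues = topo.residue_keys()
    counts = {}
    for f in range(traj.n_frames):
        for i, ri in enumerate(residues):
            for rj in residues[i + 1:]:
                if ri[0] == rj[0] and abs(ri[1] - rj[1]) < min_seq_sep:
                    continue
                mi = sc & (topo.chain == ri[0]) & (topo.resnum == ri[1])
                mj = sc & (topo.chain == rj[0]) & (topo.resnum == rj[1])
                if not (mi.any() and mj.any()):
                    continue
                d = np.linalg.norm(
                    traj.xyz[f][mi][:, None, :] - traj.xyz[f][mj][None, :, :], axis=2
                )
                if d.min() <= cutoff:
                    counts[(ri, rj)] = counts.get((ri, rj), 0) + 1
    return {k: v / traj.n_frames for k, v in counts.items()}


class TestContactPersistence:
    def test_pair_held_in_contact_has_persistence_one(self):
        ref = make_reference_structure(20)
        spec = TrajectorySpec(
            n_residues=20, n_frames=30, per_residue_sigma=0.0,
            contact_schedule=(((5, 15), 1.0),),
        )
        traj = gen_trajectory(spec, ref)
        recs = {(r.residue_i[1], r.residue_j[1]): r.persistence
                for r in contact_persistence(traj)}
        assert recs[(5, 15)] == 1.0

    def test_adjacent_residues_excluded_by_sequence_rule(self):
        # spacing 4.0 A puts neighbouring side chains within the cutoff,
        # but |i - j| = 1 pairs must not appear
        ref = make_reference_structure(10, spacing=4.0)
        spec = TrajectorySpec(n_residues=10, n_frames=5, per_residue_sigma=0.0)
        traj = gen_trajectory(spec, ref)
        recs = contact_persistence(traj)
        assert all(abs(r.residue_i[1] - r.residue_j[1]) >= 2 for r in recs)

    def test_matches_bruteforce_oracle_exactly(self):
        ref = make_reference_structure(20, chain_ids=("A", "B"))
        spec = TrajectorySpec(
            n_residues=20, chain_ids=("A", "B"), n_frames=50, per_residue_sigma=1.2,
            contact_schedule=((((("A", 4)), ("B", 12)), 0.5),), seed=21,
        )
        traj = gen_trajectory(spec, ref)
        got = {(r.residue_i, r.residue_j): r.persistence
               for r in contact_persistence(traj)}
        expected = bruteforce_contacts(traj)
        assert got == expected

    def test_glycine_contributes_no_contacts(self):
        ref = make_reference_structure(10, spacing=4.0, gly_positions=(4,))
        spec = TrajectorySpec(n_residues=10, n_frames=5, per_residue_sigma=0.0)
        traj = gen_trajectory(spec, ref)
        for r in contact_persistence(traj):
            assert 4 not in (r.residue_i[1], r.residue_j[1])

    def test_records_canonically_ordered_and_bounded(self):
        with pytest.raises(ValueError, match="canonically ordered"):
            ContactRecord(("B", 5), ("A", 9), 0.5)
        with pytest.raises(ValueError, match="persistence"):
            ContactRecord(("A", 5), ("A", 9), 1.5)


class TestRegionContactFrequency:
    def _records(self, persistences):
        return [
            ContactRecord(("A", 36 + i), ("A", 60 + i), p)
            for i, p in enumerate(persistences)
        ]

    def test_counts_and_mean(self):
        recs = self._records([0.4, 0.6, 0.8])
        out = region_contact_frequency(recs, range(36, 41), "A")
        assert out["count"] == 3
        assert out["mean_persistence"] == pytest.approx(0.6)

    def test_region_without_contacts(self):
        recs = self._records([0.4])
        out = region_contact_frequency(recs, range(100, 110), "A")
        assert out["count"] == 0
        assert out["mean_persistence"] == 0.0

    def test_constructed_persistence_drop_measured(self):
        a = self._records([0.8, 0.8, 0.8])
        b = self._records([0.5, 0.5, 0.5])
        region = range(36, 41)
        diff = (
            region_contact_frequency(a, region, "A")["mean_persistence"]
            - region_contact_frequency(b, region, "A")["mean_persistence"]
        )
        assert diff == pytest.approx(0.3, abs=1e-12)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            region_contact_frequency([], [], "A")


class TestHbondDistance:
    def _model_with_pair(self, d=2.90):
        ref = make_reference_structure(10, chain_ids=("A",))
        xyz = ref.xyz.copy()
        # place O of residue 7 at distance d from N of residue 3
        n_idx = np.flatnonzero((ref.resnum == 3) & (ref.name == "N"))[0]
        o_idx = np.flatnonzero((ref.resnum == 7) & (ref.name == "O"))[0]
        xyz[o_idx] = xyz[n_idx] + np.array([0.0, 0.0, d])
        return StructureModel(
            ref.chain, ref.resnum, ref.resname, ref.name, ref.element,
            xyz, ref.bfactor, ref.occupancy,
        )

    def test_constructed_distance_returned(self):
        model = self._model_with_pair(2.90)
        out = hbond_distance(model, 3, 7)
        assert out[0]["distance"] == pytest.approx(2.90, abs=1e-9)
        assert out[0]["atomA"] == "3/N" and out[0]["atomB"] == "7/O"

    def test_same_residue_self_pairs_excluded(self):
        model = self._model_with_pair()
        out = hbond_distance(model, 3, 3)
        assert all(r["distance"] > 0 for r in out)

    def test_missing_atom_listed_in_error(self):
        ref = make_reference_structure(5)
        keep = ~((ref.resnum == 2) & (ref.name == "O"))
        model = ref.select(keep)
        with pytest.raises(ValueError, match="A/2/O"):
            hbond_distance(model, 2, 4)

    def test_results_sorted_ascending(self):
        out = hbond_distance(self._model_with_pair(), 3, 7)
        d = [r["distance"] for r in out]
        assert d == sorted(d)


class TestBfactorProfile:
    def _model(self, b_bc=20.0, b_other=20.0):
        ref = make_reference_structure(50)
        b = np.full(ref.n_atoms, b_other)
        bc = (ref.resnum >= 36) & (ref.resnum <= 40)
        b[bc] = b_bc
        return StructureModel(
            ref.chain, ref.resnum, ref.resname, ref.name, ref.element,
            ref.xyz, b, ref.occupancy,
        )

    def test_uniform_b_gives_unit_ratio(self):
        out = bfactor_profile(self._model())
        assert out["region_ratio"]["A"]["BC"] == pytest.approx(1.0)

    def test_doubled_bc_loop_measured_against_background(self):
        out = bfactor_profile(self._model(b_bc=40.0, b_other=20.0))
        prof = out["per_chain"]["A"]
        bc = (prof["resnum"] >= 36) & (prof["resnum"] <= 40)
        ratio_vs_background = prof["b"][bc].mean() / prof["b"][~bc].mean()
        assert ratio_vs_background == pytest.approx(2.0)
        assert out["region_means"]["A"]["BC"] == pytest.approx(40.0)
        assert out["region_ratio"]["A"]["BC"] > 1.0

    def test_residue_without_ca_skipped(self):
        model = self._model()
        keep = ~((model.resnum == 10) & (model.name == "CA"))
        out = bfactor_profile(model.select(keep))
        assert 10 not in out["per_chain"]["A"]["resnum"]


class TestPDBIO:
    def test_structure_roundtrip(self, tmp_path):
        ref = make_reference_structure(12, chain_ids=("A", "B"))
        model = StructureModel(
            ref.chain, ref.resnum, ref.resname, ref.name, ref.element,
            ref.xyz, np.linspace(5.0, 50.0, ref.n_atoms), ref.occupancy,
        )
        path = tmp_path / "model.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.atom_keys() == model.atom_keys()
        np.testing.assert_allclose(back.xyz, model.xyz, atol=1.5e-3)
        np.testing.assert_allclose(back.bfactor, model.bfactor, atol=5e-3)

    def test_trajectory_roundtrip(self, tmp_path):
        ref = make_reference_structure(6)
        spec = TrajectorySpec(n_residues=6, n_frames=5, per_residue_sigma=0.2, seed=2)
        traj = gen_trajectory(spec, ref)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.xyz, traj.xyz, atol=1.5e-3)
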