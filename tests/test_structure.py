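"""Superposition RMSD, H-bond geometry, occupancy, RMSF, PDB round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from slidepull.structure import (
    HBondCriteria,
    StructureModel,
    Trajectory,
    assign_donors_acceptors,
    detect_hbonds,
    hbond_occupancy,
    pair_calpha,
    read_structure,
    read_trajectory,
    rmsf,
    rmsf_ratio,
    superpose_rmsd,
    write_structure,
    write_trajectory,
)


def _model(atoms):
    """atoms: list of (element, name, resname, resseq, chain, (x, y, z))."""
    el, nm, rn, rs, ch, xyz = zip(*atoms)
    return StructureModel(np.array(el), np.array(nm), np.array(rn),
                          np.array(rs, dtype=int), np.array(ch),
                          np.array(xyz, dtype=float))


def _rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


class TestSuperposition:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 30, (40, 3))
        rmsd, R, t = superpose_rmsd(a, a)
        assert rmsd < 1e-12
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 30, (40, 3))
        Rt = _rotation([1, 2, 3], 1.1)
        b = a @ Rt.T + np.array([5.0, -3.0, 12.0])
        rmsd, R, t = superpose_rmsd(a, b)
        assert rmsd < 1e-10
        np.testing.assert_allclose(b @ R.T + t, a, atol=1e-9)
        np.testing.assert_allclose(R @ Rt, np.eye(3), atol=1e-9)

    def test_global_optimum_vs_random_rotation_search(self):
        # Kabsch RMSD must not exceed that of any other rotation (with the
        # optimal translation, i.e. matched centroids) — brute-force check
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 20, (4, 3))
        b = a @ _rotation([0, 0, 1], 0.7).T + rng.normal(0, 1.0, (4, 3))
        best, _, _ = superpose_rmsd(a, b)
        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)
        for _ in range(3000):
            axis = rng.normal(size=3)
            R = _rotation(axis, rng.uniform(0, 2 * math.pi))
            trial = float(np.sqrt(np.mean(np.sum((b0 @ R.T - a0) ** 2, axis=1))))
            assert best <= trial + 1e-12

    def test_reflection_not_allowed(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 20, (30, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirror image
        rmsd, R, _ = superpose_rmsd(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 1.0  # cannot be superposed by a proper rotation

    def test_collinear_rejected(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose_rmsd(a, a)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def _ca_chain(resnames, resseqs, chain="A", offset=0.0):
    rng = np.random.default_rng(hash(chain) % 2 ** 31)
    return [("C", "CA", rn, rs, chain,
             (3.8 * i + offset, (i % 3) * 1.0, (i % 2) * 1.5))
            for i, (rn, rs) in enumerate(zip(resnames, resseqs))]


class TestPairCalpha:
    def test_resnum_pairing_uses_common_numbers(self):
        a = _model(_ca_chain(["ALA"] * 6, [1, 2, 3, 4, 5, 6]))
        b = _model(_ca_chain(["ALA"] * 4, [3, 4, 5, 6]))
        ca, cb, n = pair_calpha(a, b, alignment="resnum")
        assert n == 4
        np.testing.assert_allclose(ca, a.coords[2:6])

    def test_sequence_pairing_survives_renumbering(self):
        names = ["MET", "LYS", "VAL", "PHE", "GLY", "SER", "TRP", "GLU"]
        a = _model(_ca_chain(names, range(1, 9)))
        b = _model(_ca_chain(names, range(101, 109)))  # disjoint numbering
        with pytest.raises(ValueError):
            pair_calpha(a, b, alignment="resnum")
        ca, cb, n = pair_calpha(a, b, alignment="sequence")
        assert n == 8

    def test_sequence_pairing_handles_deletion(self):
        names = ["MET", "LYS", "VAL", "PHE", "GLY", "SER", "TRP", "GLU"]
        a = _model(_ca_chain(names, range(1, 9)))
        short = names[:3] + names[4:]  # PHE deleted
        b = _model(_ca_chain(short, range(1, 8)))
        ca, cb, n = pair_calpha(a, b, alignment="sequence")
        assert n == 7

    def test_unknown_alignment(self):
        a = _model(_ca_chain(["ALA"] * 5, range(1, 6)))
        with pytest.raises(ValueError, match="alignment"):
            pair_calpha(a, a, alignment="magic")

    def test_no_calpha(self):
        m = _model([("O", "O", "HOH", 1, "W", (0, 0, 0))])
        with pytest.raises(ValueError, match="C-alpha"):
            pair_calpha(m, m)


def _hbond_fixture(acceptor_pos, with_hydrogen=True):
    atoms = [
        ("N", "N", "ALA", 1, "A", (0.0, 0.0, 0.0)),       # donor (backbone N)
        ("O", "O", "GLY", 2, "A", acceptor_pos),           # acceptor
    ]
    if with_hydrogen:
        atoms.append(("H", "H", "ALA", 1, "A", (1.0, 0.0, 0.0)))
    return _model(atoms)


class TestHBonds:
    # acceptor at 2.6 A from H along a direction making a 150 deg
    # acceptor...H-donor angle: donor-acceptor distance 3.50 A
    GOOD = (1.0 + 2.6 * math.cos(math.radians(30)), 2.6 * math.sin(math.radians(30)), 0.0)

    def test_good_geometry_gives_bond(self):
        bonds = detect_hbonds(_hbond_fixture(self.GOOD))
        assert len(bonds) == 1
        b = bonds[0]
        assert b.distance == pytest.approx(3.50, abs=0.01)
        assert b.angle == pytest.approx(150.0, abs=0.5)
        assert b.hydrogen_index == 2

    def test_distance_beyond_cutoff(self):
        far = (3.45, 1.38, 0.0)  # 3.72 A donor-acceptor
        assert math.hypot(*far[:2]) > 3.6
        assert detect_hbonds(_hbond_fixture(far)) == []

    def test_angle_outside_range(self):
        # 100 deg at the hydrogen, distance well inside the cutoff
        pos = (1.0 + 2.0 * math.cos(math.radians(80)), 2.0 * math.sin(math.radians(80)), 0.0)
        model = _hbond_fixture(pos)
        assert detect_hbonds(model) == []
        # the same geometry passes in crystal (distance-only) mode
        no_h = _hbond_fixture(pos, with_hydrogen=False)
        assert len(detect_hbonds(no_h)) == 1

    def test_crystal_mode_distance_only(self):
        model = _hbond_fixture(self.GOOD, with_hydrogen=False)
        bonds = detect_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].hydrogen_index is None and bonds[0].angle is None

    def test_require_hydrogens_raises_with_guidance(self):
        model = _hbond_fixture(self.GOOD, with_hydrogen=False)
        with pytest.raises(ValueError, match="crystal mode"):
            detect_hbonds(model, require_hydrogens=True)

    def test_same_residue_pairs_skipped(self):
        atoms = [("N", "N", "SER", 1, "A", (0.0, 0.0, 0.0)),
                 ("O", "OG", "SER", 1, "A", (2.8, 0.0, 0.0))]
        assert detect_hbonds(_model(atoms)) == []

    def test_donor_without_hydrogen_excluded_in_md_mode(self):
        # hydrogens exist in the model but not on this donor
        atoms = [("N", "N", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                 ("O", "O", "GLY", 2, "A", (3.0, 0.0, 0.0)),
                 ("H", "H", "GLY", 3, "A", (20.0, 0.0, 0.0))]
        assert detect_hbonds(_model(atoms)) == []

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_donor_acceptor_distance=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(angle_min=150.0, angle_max=120.0)


class TestDonorAcceptorAssignment:
    def test_standard_residue_rules(self):
        m = _model([
            ("N", "N", "ALA", 1, "A", (0, 0, 0)),     # backbone: donor
            ("O", "O", "ALA", 1, "A", (2, 0, 0)),     # carbonyl: acceptor only
            ("O", "OG", "SER", 2, "A", (4, 0, 0)),    # hydroxyl: donor
            ("C", "CB", "SER", 2, "A", (6, 0, 0)),    # carbon: neither
            ("O", "O", "HOH", 3, "W", (8, 0, 0)),     # water: both
            ("O", "O3", "LIG", 1, "B", (10, 0, 0)),   # sugar O: both
        ])
        donor, acceptor = assign_donors_acceptors(m)
        assert donor.tolist() == [True, False, True, False, True, True]
        assert acceptor.tolist() == [True, True, True, False, True, True]


class TestOccupancy:
    def test_half_occupancy(self):
        top = _hbond_fixture((3.0, 0.0, 0.0), with_hydrogen=False)
        near = top.coords.copy()
        far = top.coords.copy()
        far[1, 0] = 8.0  # acceptor out of range in alternate frames
        frames = np.stack([near, far, near, far])
        occ = hbond_occupancy(Trajectory(top, frames))
        assert occ == {(0, 1): 0.5}

    def test_minimum_frames(self):
        top = _hbond_fixture((3.0, 0.0, 0.0), with_hydrogen=False)
        with pytest.raises(ValueError, match="2 frames"):
            hbond_occupancy(Trajectory(top, top.coords[None]))


class TestRMSF:
    def _rigid_traj(self, n_frames=8):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 20, (10, 3))
        top = _model([("C", "CA", "ALA", i + 1, "A", tuple(base[i]))
                      for i in range(10)])
        frames = []
        for _ in range(n_frames):
            R = _rotation(rng.normal(size=3), rng.uniform(0, 1.0))
            frames.append(base @ R.T + rng.uniform(-5, 5, 3))
        return Trajectory(top, np.stack(frames))

    def test_rigid_body_motion_gives_zero_rmsf(self):
        traj = self._rigid_traj()
        series = rmsf(traj, np.ones(10, dtype=bool))
        assert np.all(series.to_numpy() < 1e-8)
        assert series.index.names == ["chain", "resseq"]

    def test_validation(self):
        traj = self._rigid_traj(2)
        with pytest.raises(ValueError, match="alignment"):
            rmsf(traj, np.zeros(10, dtype=bool))
        with pytest.raises(ValueError, match="frames"):
            rmsf(Trajectory(traj.topology, traj.frames[:1]),
                 np.ones(10, dtype=bool))

    def test_ratio_excludes_zero_complex(self):
        idx = pd.MultiIndex.from_tuples([("A", 1), ("A", 2), ("A", 3)],
                                        names=["chain", "resseq"])
        apo = pd.Series([2.0, 3.0, 1.0], index=idx)
        com = pd.Series([1.0, 1.5, 0.0], index=idx)
        ratios, mean = rmsf_ratio(apo, com)
        assert ratios.loc[("A", 1)] == 2.0
        assert np.isnan(ratios.loc[("A", 3)])
        assert mean == pytest.approx(2.0)

    def test_ratio_residue_subset(self):
        idx = pd.MultiIndex.from_tuples([("A", 1), ("A", 2)],
                                        names=["chain", "resseq"])
        apo = pd.Series([2.0, 4.0], index=idx)
        com = pd.Series([1.0, 1.0], index=idx)
        _, mean = rmsf_ratio(apo, com, residues=[("A", 2)])
        assert mean == pytest.approx(4.0)
        with pytest.raises(ValueError, match="absent"):
            rmsf_ratio(apo, com, residues=[("B", 9)])


class TestPDBIO:
    def test_structure_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        atoms = [("N", "N", "ALA", 1, "A", tuple(rng.uniform(0, 50, 3))),
                 ("C", "CA", "ALA", 1, "A", tuple(rng.uniform(0, 50, 3))),
                 ("O", "O", "HOH", 2, "W", tuple(rng.uniform(0, 50, 3)))]
        m = _model(atoms)
        p = tmp_path / "m.pdb"
        write_structure(m, p)
        back = read_structure(p)
        assert len(back) == 3
        np.testing.assert_array_equal(back.name, m.name)
        np.testing.assert_array_equal(back.resname, m.resname)
        np.testing.assert_array_equal(back.resseq, m.resseq)
        np.testing.assert_array_equal(back.chain, m.chain)
        # PDB stores 3 decimals
        np.testing.assert_allclose(back.coords, m.coords, atol=1e-3)

    def test_trajectory_roundtrip(self, tmp_path):
        top = _model([("C", "CA", "ALA", i + 1, "A", (float(i), 0.0, 0.0))
                      for i in range(4)])
        frames = np.stack([top.coords + s for s in (0.0, 0.25, 0.5)])
        p = tmp_path / "t.pdb"
        write_trajectory(Trajectory(top, frames), p)
        back = read_trajectory(p)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.frames, frames, atol=1e-3)
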