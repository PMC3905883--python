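"""Structural statistics: RMSF, H-bonds, superposed RMSD, clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from metafes.landscape import StateAssignment
from metafes.structure import (
    HBondCriteria,
    detect_hbonds,
    gromos_cluster,
    hbond_percentages,
    nick_width,
    rmsd_superposed,
    rmsf,
)
from metafes.synthetic import generate_mock_trajectory
from metafes.system import Atom, Topology, Trajectory


def simple_top(n, donors=(), acceptors=()):
    atoms = [Atom(f"A{i}", "C", 12.0, i, "RES") for i in range(n)]
    return Topology(atoms=atoms, donors=list(donors), acceptors=list(acceptors))


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        top = simple_top(4)
        coords = np.tile(np.arange(12.0).reshape(1, 4, 3), (5, 1, 1))
        traj = Trajectory(coords=coords, times=np.arange(5.0))
        table = rmsf(traj, top, fit=False)
        assert np.allclose(table["rmsf"], 0.0)

    def test_two_position_oscillator_is_one_nm(self):
        top = simple_top(1)
        coords = np.zeros((10, 1, 3))
        coords[1::2, 0, 2] = 2.0  # alternate z = 0 and 2 -> deviations +-1
        traj = Trajectory(coords=coords, times=np.arange(10.0))
        table = rmsf(traj, top, fit=False)
        assert table["rmsf"].iloc[0] == pytest.approx(1.0)

    def test_residue_combines_atom_rmsfs_in_quadrature(self):
        # two equal-mass atoms in one residue with RMSFs a and b
        atoms = [Atom("A0", "C", 12.0, 0, "RES"), Atom("A1", "C", 12.0, 0, "RES")]
        top = Topology(atoms=atoms)
        coords = np.zeros((10, 2, 3))
        coords[1::2, 0, 2] = 2.0  # atom 0: rmsf 1.0
        coords[1::2, 1, 2] = 1.0  # atom 1: rmsf 0.5
        traj = Trajectory(coords=coords, times=np.arange(10.0))
        table = rmsf(traj, top, fit=False)
        assert table["rmsf"].iloc[0] == pytest.approx(
            np.sqrt((1.0**2 + 0.5**2) / 2)
        )

    def test_translation_invariant(self, rng):
        top = simple_top(5)
        coords = rng.normal(size=(8, 5, 3))
        traj1 = Trajectory(coords=coords, times=np.arange(8.0))
        traj2 = Trajectory(coords=coords + np.array([3.0, -1.0, 2.0]),
                           times=np.arange(8.0))
        t1 = rmsf(traj1, top, fit=False)
        t2 = rmsf(traj2, top, fit=False)
        np.testing.assert_allclose(t1["rmsf"], t2["rmsf"], rtol=1e-12)

    def test_single_frame_rejected(self):
        top = simple_top(2)
        traj = Trajectory(coords=np.zeros((1, 2, 3)), times=np.zeros(1))
        with pytest.raises(ValueError):
            rmsf(traj, top)

    def test_fit_removes_rigid_drift(self, rng):
        top = simple_top(6)
        base = rng.normal(size=(6, 3))
        frames = []
        for f in range(12):
            rot = Rotation.from_rotvec([0.02 * f, 0.0, 0.01 * f])
            frames.append(rot.apply(base) + f * np.array([0.5, 0.0, 0.0]))
        traj = Trajectory(coords=np.stack(frames), times=np.arange(12.0))
        fitted = rmsf(traj, top, fit=True)
        raw = rmsf(traj, top, fit=False)
        assert fitted["rmsf"].max() < 1e-8
        assert raw["rmsf"].max() > 0.5


class TestDetectHbonds:
    def build(self, da=0.30, angle_deg=0.0):
        top = simple_top(3, donors=[(0, 1)], acceptors=[2])
        frame = np.zeros((3, 3))
        # hydrogen along +x; acceptor at distance da, rotated off-axis
        frame[1] = [0.1, 0.0, 0.0]
        th = np.radians(angle_deg)
        frame[2] = [da * np.cos(th), da * np.sin(th), 0.0]
        return frame, top

    def test_colinear_inside_cutoffs_detected(self):
        frame, top = self.build(0.30, 0.0)
        assert detect_hbonds(frame, top) == [(0, 1, 2)]

    def test_distance_gate(self):
        frame, top = self.build(0.36, 0.0)
        assert detect_hbonds(frame, top) == []

    def test_angle_gate(self):
        frame, top = self.build(0.30, 45.0)
        assert detect_hbonds(frame, top) == []
        frame, top = self.build(0.30, 29.0)
        assert detect_hbonds(frame, top) == [(0, 1, 2)]

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            HBondCriteria(distance_cutoff=-0.1)


class TestHbondPercentages:
    def test_always_present_pair_is_100(self, tiny_mock_spec):
        from metafes.synthetic import MockComplexSpec

        spec = MockComplexSpec(
            atoms=tiny_mock_spec.atoms,
            states=["B"],
            occupancy={("ND", "LO", "B"): 1.0},
            sigma=tiny_mock_spec.sigma,
            state_sequence=["B"] * 40,
            seed=2,
        )
        top, traj = generate_mock_trajectory(spec, 40)
        states = StateAssignment(labels=["B"] * 40, delta_f=np.zeros(40),
                                 cutoff=20.0)
        table = hbond_percentages(traj, top, states)
        assert len(table) == 1
        assert table["B"].iloc[0] == pytest.approx(100.0)

    def test_binomial_recovery_and_threshold_filter(self, tiny_mock_spec):
        top, traj = generate_mock_trajectory(tiny_mock_spec, 500)
        states = StateAssignment(
            labels=list(tiny_mock_spec.state_sequence[:500]),
            delta_f=np.zeros(500), cutoff=20.0,
        )
        table = hbond_percentages(traj, top, states)
        assert len(table) == 1  # kept because B > 25%
        row = table.iloc[0]
        se = 100 * np.sqrt(0.49 * 0.51 / 400)
        assert abs(row["B"] - 49.0) <= 3 * se
        assert row["I"] == 0.0 and row["Ts"] == 0.0

    def test_low_occupancy_row_dropped(self, tiny_mock_spec):
        from metafes.synthetic import MockComplexSpec

        spec = MockComplexSpec(
            atoms=tiny_mock_spec.atoms,
            states=["B"],
            occupancy={("ND", "LO", "B"): 0.10},
            sigma=tiny_mock_spec.sigma,
            state_sequence=["B"] * 300,
            seed=4,
        )
        top, traj = generate_mock_trajectory(spec, 300)
        states = StateAssignment(labels=["B"] * 300, delta_f=np.zeros(300),
                                 cutoff=20.0)
        table = hbond_percentages(traj, top, states)
        assert len(table) == 0


class TestRmsdSuperposed:
    def test_identical_frames_zero(self, rng):
        a = rng.normal(size=(6, 3))
        assert rmsd_superposed(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self, rng):
        a = rng.normal(size=(8, 3))
        rot = Rotation.from_rotvec([0.4, -0.2, 1.1])
        b = rot.apply(a) + np.array([1.0, 2.0, -0.5])
        assert rmsd_superposed(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_matches_mdanalysis_reference(self, rng):
        from MDAnalysis.analysis import rms as mda_rms

        a = rng.normal(size=(7, 3))
        b = a + rng.normal(0, 0.1, size=(7, 3))
        w = rng.uniform(1, 16, 7)
        ours = rmsd_superposed(a, b, masses=w)
        ref = mda_rms.rmsd(a, b, weights=w, center=True, superposition=True)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_symmetry(self, rng):
        a = rng.normal(size=(5, 3))
        b = a + rng.normal(0, 0.2, size=(5, 3))
        assert rmsd_superposed(a, b) == pytest.approx(
            rmsd_superposed(b, a), rel=1e-9
        )

    def test_collinear_rejected(self):
        a = np.zeros((3, 3))
        a[:, 0] = [0.0, 1.0, 2.0]
        with pytest.raises(ValueError):
            rmsd_superposed(a, a)


class TestGromosCluster:
    def traj_from(self, frames):
        frames = np.asarray(frames, dtype=float)
        return Trajectory(coords=frames, times=np.arange(len(frames), dtype=float))

    def test_identical_frames_one_cluster(self, rng):
        base = rng.normal(size=(5, 3))
        traj = self.traj_from([base] * 6)
        res = gromos_cluster(traj, cutoff=0.1)
        assert len(res.clusters) == 1
        assert res.clusters[0] == list(range(6))

    def test_two_blob_membership_exact(self, rng):
        base = rng.normal(size=(5, 3))
        shifted = base.copy()
        shifted[0] += [1.5, 0.0, 0.0]  # non-rigid deformation, RMSD ~ 0.6
        frames = []
        labels = []
        for k in range(8):
            if k % 2 == 0:
                frames.append(base + rng.normal(0, 0.005, (5, 3)))
                labels.append(0)
            else:
                frames.append(shifted + rng.normal(0, 0.005, (5, 3)))
                labels.append(1)
        res = gromos_cluster(self.traj_from(frames), cutoff=0.1)
        assert len(res.clusters) == 2
        got = [set(c) for c in res.clusters]
        expect = [
            {k for k in range(8) if labels[k] == 0},
            {k for k in range(8) if labels[k] == 1},
        ]
        assert got[0] in expect and got[1] in expect and got[0] != got[1]
        for ci, members in enumerate(res.clusters):
            assert res.representatives[ci] in members

    def test_matches_greedy_brute_force(self, rng):
        frames = rng.normal(size=(8, 4, 3))
        traj = self.traj_from(frames)
        cutoff = 0.9
        res = gromos_cluster(traj, cutoff=cutoff)
        dm = res.rmsd_matrix
        remaining = set(range(8))
        expected = []
        while remaining:
            best = max(
                sorted(remaining),
                key=lambda i: (sum(dm[i, j] <= cutoff for j in remaining),
                               -i),
            )
            members = sorted(j for j in remaining if dm[best, j] <= cutoff)
            expected.append(members)
            remaining -= set(members)
        expected.sort(key=lambda c: -len(c))
        assert [sorted(c) for c in res.clusters] == expected

    def test_sizes_non_increasing_and_partition(self, rng):
        frames = rng.normal(size=(10, 4, 3)) * 0.4
        res = gromos_cluster(self.traj_from(frames), cutoff=0.5)
        sizes = [len(c) for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)
        allm = sorted(m for c in res.clusters for m in c)
        assert allm == list(range(10))


class TestNickWidth:
    def base_top(self):
        atoms = [
            Atom("Bm1a", "C", 12.0, 0, "DB", kind="base", base_position=-1,
                 strand="intact"),
            Atom("Bm1b", "C", 12.0, 1, "DB", kind="base", base_position=-1,
                 strand="scissile"),
            Atom("Bp1a", "C", 12.0, 2, "DB", kind="base", base_position=1,
                 strand="intact"),
            Atom("Bp1b", "C", 12.0, 3, "DB", kind="base", base_position=1,
                 strand="scissile"),
        ]
        return Topology(atoms=atoms)

    def test_constructed_separation(self):
        top = self.base_top()
        frame = np.zeros((4, 3))
        frame[0] = [0.1, 0, 1.2]
        frame[1] = [-0.1, 0, 1.2]  # -1 COM at (0, 0, 1.2)
        frame[2] = [0.1, 0, 0.0]
        frame[3] = [-0.1, 0, 0.0]  # +1 COM at origin
        assert nick_width(frame, top) == pytest.approx(1.2)

    def test_rigid_motion_invariant(self, rng):
        top = self.base_top()
        frame = rng.normal(size=(4, 3))
        rot = Rotation.from_rotvec([0.2, 0.9, -0.4])
        moved = rot.apply(frame) + np.array([2.0, -1.0, 0.7])
        assert nick_width(moved, top) == pytest.approx(
            nick_width(frame, top), rel=1e-12
        )

    def test_delegates_to_com_distance(self, rng):
        from metafes.cvs import AtomGroup, com_distance

        top = self.base_top()
        frame = rng.normal(size=(4, 3))
        direct = com_distance(
            frame, AtomGroup((0, 1)), AtomGroup((2, 3)), top.masses
        )
        assert nick_width(frame, top) == pytest.approx(direct, rel=1e-12)

    def test_missing_labels_rejected(self):
        top = simple_top(3)
        with pytest.raises(ValueError):
            nick_width(np.zeros((3, 3)), top)
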