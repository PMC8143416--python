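"""Superposition, RMSD series, AUC difference, gromos clustering and
the periodic-image check."""

import numpy as np
import pytest

from oracles import brute_force_gromos, horn_quaternion_rmsd, pairwise_fitted_rmsd_matrix
from ptmimpact import synthetic
from ptmimpact.conformation import (
    AtomLabel,
    Box,
    ClusterParams,
    Frame,
    RMSDSeries,
    Trajectory,
    gromos_cluster,
    kabsch_superpose,
    periodic_image_min_distance,
    read_xyz_trajectory,
    rmsd_auc_difference,
    rmsd_series,
    write_xyz_trajectory,
)


def labels(n, backbone_every=1):
    return tuple(
        AtomLabel("A", i + 1, "CA", (i % backbone_every) == 0) for i in range(n)
    )


def cloud(n, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 5.0


def rotation_z(deg):
    t = np.deg2rad(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
    )


class TestKabsch:
    def test_identical_frames_zero_rmsd(self):
        x = cloud(10)
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_translation_invariance(self):
        x = cloud(10)
        _, _, rmsd = kabsch_superpose(x, x + np.array([3.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_recovered(self):
        x = cloud(12, seed=3)
        moved = x @ rotation_z(73.0).T + np.array([1.0, -2.0, 0.5])
        _, _, rmsd = kabsch_superpose(x, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle_with_noise(self):
        rng = np.random.default_rng(4)
        x = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        moved = x @ rotation_z(90.0).T + rng.normal(0, 0.2, size=x.shape)
        _, _, rmsd = kabsch_superpose(x, moved)
        assert rmsd == pytest.approx(horn_quaternion_rmsd(x, moved), abs=1e-9)

    def test_rotation_is_proper_even_for_mirrored_input(self):
        x = cloud(8, seed=9)
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(x, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        a, b = cloud(15, seed=1), cloud(15, seed=2)
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], abs=1e-9
        )

    def test_collinear_geometry_is_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


def make_traj(coord_list, times=None):
    lab = labels(len(coord_list[0]))
    frames = tuple(Frame(coords=c, labels=lab) for c in coord_list)
    if times is None:
        times = np.arange(1.0, len(frames) + 1)
    return Trajectory(frames=frames, times=times)


class TestRMSDSeries:
    def test_copies_of_reference_give_zero(self):
        x = cloud(10)
        traj = make_traj([x, x, x])
        series = rmsd_series(traj, traj.frames[0], selection="all_atoms")
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_fit_removes_uniform_shift(self):
        x = cloud(10)
        traj = make_traj([x + np.array([3.0, 0, 0])])
        series = rmsd_series(traj, Frame(coords=x, labels=labels(10)), "all_atoms")
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_unfitted_shift_is_three_angstrom(self):
        x = cloud(10)
        traj = make_traj([x + np.array([3.0, 0, 0])])
        series = rmsd_series(
            traj, Frame(coords=x, labels=labels(10)), "all_atoms", fit=False
        )
        assert series.values[0] == pytest.approx(3.0)

    def test_fitted_never_exceeds_unfitted(self):
        rng = np.random.default_rng(8)
        x = cloud(20)
        frames = [x + rng.normal(0, 1.0, size=x.shape) for _ in range(5)]
        traj = make_traj(frames)
        ref = Frame(coords=x, labels=labels(20))
        fitted = rmsd_series(traj, ref, "all_atoms", fit=True).values
        raw = rmsd_series(traj, ref, "all_atoms", fit=False).values
        assert np.all(fitted <= raw + 1e-9)


class TestAUCDifference:
    def series(self, values, times=None):
        values = np.asarray(values, float)
        if times is None:
            times = np.linspace(0.0, 10_000.0, len(values))
        return RMSDSeries(times=times, values=values, selection="backbone")

    def test_constant_difference(self):
        sm = self.series(np.full(11, 2.0))
        sn = self.series(np.full(11, 1.0))
        assert rmsd_auc_difference(sm, sn) == pytest.approx(1.0)

    def test_identical_series_give_zero(self):
        s = self.series(np.linspace(0, 3, 11))
        assert rmsd_auc_difference(s, s) == pytest.approx(0.0)

    def test_ramp_vs_constant_cancels(self):
        # trapezoid area of a 0->2 ramp equals that of a constant 1
        sm = self.series(np.linspace(0, 2, 21))
        sn = self.series(np.full(21, 1.0))
        assert rmsd_auc_difference(sm, sn) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric(self):
        rng = np.random.default_rng(3)
        sm = self.series(rng.uniform(0, 4, 16))
        sn = self.series(rng.uniform(0, 4, 16))
        assert rmsd_auc_difference(sm, sn) == pytest.approx(
            -rmsd_auc_difference(sn, sm), abs=1e-12
        )

    def test_mismatched_spans_error(self):
        sm = self.series(np.ones(5), times=np.linspace(0, 10, 5))
        sn = self.series(np.ones(5), times=np.linspace(0, 20, 5))
        with pytest.raises(ValueError, match="span"):
            rmsd_auc_difference(sm, sn)


class TestGromosClustering:
    def test_identical_frames_single_cluster(self):
        x = cloud(10)
        result = gromos_cluster(make_traj([x, x, x, x]))
        assert len(result.clusters) == 1
        members, center = result.clusters[0]
        assert members == (0, 1, 2, 3) and center == 0  # lowest-index tie-break

    def test_two_separated_groups(self):
        rng = np.random.default_rng(5)
        a = cloud(10, seed=1)
        b = a + rng.normal(0, 10.0, size=a.shape)  # far beyond the cutoff
        frames = [a, a + rng.normal(0, 0.05, a.shape), b, b + rng.normal(0, 0.05, a.shape)]
        result = gromos_cluster(make_traj(frames))
        partitions = sorted(sorted(m) for m, _ in result.clusters)
        assert partitions == [[0, 1], [2, 3]]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            base = cloud(8, seed=trial)
            frames = [base + rng.normal(0, 1.2, base.shape) for _ in range(10)]
            traj = make_traj(frames)
            params = ClusterParams(cutoff_nm=0.25)
            got = gromos_cluster(traj, params).clusters
            dist = pairwise_fitted_rmsd_matrix([f.coords for f in traj.frames])
            expected = brute_force_gromos(dist, params.cutoff_angstrom)
            assert [set(m) for m, _ in got] == [set(m) for m, _ in expected]
            assert [c for _, c in got] == [c for _, c in expected]

    def test_partition_invariants(self):
        rng = np.random.default_rng(7)
        base = cloud(8, seed=2)
        frames = [base + rng.normal(0, 1.5, base.shape) for _ in range(15)]
        result = gromos_cluster(make_traj(frames))
        sizes = [len(m) for m, _ in result.clusters]
        assert sizes == sorted(sizes, reverse=True)
        all_members = [i for m, _ in result.clusters for i in m]
        assert sorted(all_members) == list(range(15))


class TestPeriodicImage:
    def frame(self, coords):
        return Frame(coords=np.asarray(coords, float), labels=labels(len(coords)))

    def test_single_atom_centered(self):
        d, violated = periodic_image_min_distance(
            self.frame([[20.0, 20.0, 20.0]]), Box((40.0, 40.0, 40.0))
        )
        assert d == pytest.approx(40.0) and not violated

    def test_elongated_molecule_violates(self):
        f = self.frame([[0.0, 20.0, 20.0], [30.0, 20.0, 20.0]])
        d, violated = periodic_image_min_distance(f, Box((40.0, 40.0, 40.0)))
        assert d == pytest.approx(10.0) and violated

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        xyz = rng.uniform(5, 35, size=(50, 3))
        box = Box((40.0, 42.0, 44.0))
        d, _ = periodic_image_min_distance(self.frame(xyz), box)
        best = np.inf
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    if (i, j, k) == (0, 0, 0):
                        continue
                    shift = np.array([i, j, k]) * np.array(box.edges)
                    for a in xyz:
                        for b in xyz:
                            best = min(best, float(np.linalg.norm(a - (b + shift))))
        assert d == pytest.approx(best, abs=1e-9)

    def test_unwrapped_coordinates_error(self):
        with pytest.raises(ValueError, match="unwrapped"):
            periodic_image_min_distance(
                self.frame([[50.0, 0.0, 0.0]]), Box((40.0, 40.0, 40.0))
            )


class TestTrajectoryIO:
    def test_xyz_roundtrip(self, tmp_path, config):
        traj, _, _ = synthetic.gen_trajectory_pair(config, delta=1.0)
        path = tmp_path / "traj.xyz"
        write_xyz_trajectory(traj, path)
        back = read_xyz_trajectory(path)
        assert back.frames[0].labels == traj.frames[0].labels
        assert np.allclose(back.times, traj.times)
        for fa, fb in zip(traj.frames, back.frames):
            assert np.allclose(fa.coords, fb.coords, atol=1e-6)
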