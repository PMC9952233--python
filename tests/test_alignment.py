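import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from femurssm.alignment import (
    estimate_rigid,
    farthest_point_sample,
    icp_rigid,
    procrustes_align,
)
from femurssm.mesh import RigidTransform, TriangleMesh, apply_rigid

from conftest import icosphere


def rotation_angle_deg(R):
    return np.degrees(
        np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))
    )


class TestFarthestPointSample:
    def test_k_equals_n_returns_all_vertices(self):
        sphere = icosphere(1)
        lm = farthest_point_sample(sphere, sphere.n_vertices)
        assert sorted(lm.indices) == list(range(sphere.n_vertices))

    def test_collinear_points_pick_extremes(self):
        v = np.array([[float(i), 0.0, 0.0] for i in range(11)])
        mesh = TriangleMesh(v, np.array([[0, 1, 2]]))
        lm = farthest_point_sample(mesh, 3)
        # first point = nearest centroid (index 5), then both extremes
        assert lm.indices[0] == 5
        assert set(lm.indices[1:]) == {0, 10}

    @pytest.mark.parametrize("seed", range(10))
    def test_more_even_than_random_sampling(self, seed):
        from scipy.spatial.distance import pdist

        sphere = icosphere(3, radius=10.0)
        lm = farthest_point_sample(sphere, 50, seed=seed)
        fps_min = pdist(lm.points).min()
        rng = np.random.default_rng(seed)
        idx = rng.choice(sphere.n_vertices, 50, replace=False)
        rand_min = pdist(sphere.vertices[idx]).min()
        assert fps_min >= 0.5 * rand_min

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            farthest_point_sample(icosphere(0), 10**6)


class TestEstimateRigid:
    def test_identity_for_equal_clouds(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        t = estimate_rigid(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)

    def test_exact_recovery_of_known_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 3)) * 10
        R = Rotation.random(random_state=4).as_matrix()
        t0 = np.array([3.0, -2.0, 7.0])
        est = estimate_rigid(pts, pts @ R.T + t0)
        assert np.allclose(est.rotation, R, atol=1e-9)
        assert np.allclose(est.translation, t0, atol=1e-9)

    def test_noisy_correspondences_small_rotation_error(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(100, 3)) * 50
        R = Rotation.random(random_state=9).as_matrix()
        target = pts @ R.T + rng.normal(scale=0.1, size=pts.shape)
        est = estimate_rigid(pts, target)
        assert rotation_angle_deg(est.rotation.T @ R) < 0.2

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            estimate_rigid(line, line + 1.0)

    def test_output_is_proper_rotation(self):
        # near-degenerate input that would tempt a reflection
        rng = np.random.default_rng(3)
        src = rng.normal(size=(10, 3))
        dst = -src + rng.normal(scale=0.01, size=src.shape)
        t = estimate_rigid(src, dst)
        assert np.isclose(np.linalg.det(t.rotation), 1.0, atol=1e-9)


class TestICP:
    def test_self_alignment_is_identity(self, femur_mesh):
        res = icp_rigid(femur_mesh, femur_mesh, seed=0)
        assert res.iterations <= 2
        assert res.rms_residual < 1e-6
        assert rotation_angle_deg(res.transform.rotation) < 1e-6

    def test_recovers_rigid_perturbation(self, femur_mesh):
        R = Rotation.from_rotvec(
            np.radians(20.0) * np.array([0.3, 0.9, 0.2]) / np.sqrt(0.94)
        ).as_matrix()
        true = RigidTransform(R, np.array([10.0, -8.0, 5.0]))
        moved = apply_rigid(femur_mesh, true)
        res = icp_rigid(moved, femur_mesh, seed=1)
        err = res.transform.compose(true)
        assert rotation_angle_deg(err.rotation) < 0.5
        assert np.linalg.norm(err.translation) < 0.1

    def test_defaults_match_protocol(self):
        import inspect

        sig = inspect.signature(icp_rigid)
        assert sig.parameters["n_landmarks"].default == 50
        assert sig.parameters["max_iter"].default == 150

    def test_residual_history_non_increasing(self, femur_mesh):
        moved = apply_rigid(
            femur_mesh,
            RigidTransform(
                Rotation.from_euler("y", 10, degrees=True).as_matrix(),
                np.array([5.0, 2.0, -3.0]),
            ),
        )
        res = icp_rigid(moved, femur_mesh, seed=0)
        diffs = np.diff(res.residual_history)
        assert (diffs <= 1e-9).all()


class TestProcrustes:
    def test_pose_scatter_collapses(self):
        rng = np.random.default_rng(5)
        base = icosphere(2, radius=10.0)
        meshes = []
        for k in range(6):
            t = RigidTransform(
                Rotation.from_rotvec(
                    rng.normal(scale=0.05, size=3)
                ).as_matrix(),
                rng.normal(scale=3.0, size=3),
            )
            meshes.append(apply_rigid(base, t))
        aligned = procrustes_align(meshes)
        stack = np.stack([m.vertices for m in aligned])
        # residual scatter across the population is tiny after GPA
        assert stack.std(axis=0).max() < 1e-6


class TestAlignPopulation:
    def test_centroid_scatter_collapses_after_alignment(self, femur_mesh):
        rng = np.random.default_rng(9)
        meshes = [femur_mesh.copy()]
        for k in range(3):
            t = RigidTransform(
                Rotation.from_rotvec(
                    rng.normal(scale=0.1, size=3)
                ).as_matrix(),
                rng.normal(scale=30.0, size=3),
            )
            meshes.append(apply_rigid(femur_mesh, t))
        from femurssm.alignment import align_population

        aligned, transforms = align_population(meshes, seed=0)
        before = np.array([m.centroid() for m in meshes])
        after = np.array([m.centroid() for m in aligned])
        ss_before = ((before - before.mean(0)) ** 2).sum()
        ss_after = ((after - after.mean(0)) ** 2).sum()
        assert ss_after < 1e-6 * ss_before
        assert len(transforms) == len(meshes)
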