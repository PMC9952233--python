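import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from femurssm.mesh import RigidTransform, apply_rigid
from femurssm.morphometrics import (
    FemurAxes,
    derive_axes,
    femoral_neck_anteversion,
    fit_sphere,
    hausdorff,
    inclination_angle,
    max_femoral_length,
    measure_all,
    rotational_center_divergence,
)

from conftest import tetrahedron


def unit_sphere_points(n, radius, center, seed=0, hemisphere=False):
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    if hemisphere:
        p[:, 2] = np.abs(p[:, 2])
    return center + radius * p


class TestFitSphere:
    def test_exact_recovery(self):
        pts = unit_sphere_points(200, 20.0, np.array([1.0, 2.0, 3.0]))
        fit = fit_sphere(pts)
        assert np.allclose(fit["center"], [1, 2, 3], atol=1e-9)
        assert np.isclose(fit["radius"], 20.0, atol=1e-9)
        assert fit["rms"] < 1e-9

    def test_noisy_hemisphere(self):
        rng = np.random.default_rng(1)
        pts = unit_sphere_points(
            500, 20.0, np.zeros(3), seed=2, hemisphere=True
        )
        pts += rng.normal(scale=0.2, size=pts.shape)
        fit = fit_sphere(pts)
        assert abs(fit["radius"] - 20.0) < 0.1

    def test_coplanar_rejected(self):
        pts = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        )
        with pytest.raises(ValueError):
            fit_sphere(pts)


class TestHausdorff:
    def test_self_distance_zero(self, femur_mesh):
        assert hausdorff(femur_mesh, femur_mesh) == 0.0

    def test_translated_tetrahedron_matches_brute_force(self):
        from femurssm.validation import brute_force_hausdorff

        a = tetrahedron()
        b = apply_rigid(
            a, RigidTransform(np.eye(3), np.array([0.1, 0.0, 0.0]))
        )
        fast = hausdorff(a, b)
        slow = brute_force_hausdorff(a, b)
        assert fast == slow

    def test_symmetric_mode_invariant_under_swap(self):
        a = tetrahedron()
        b = apply_rigid(
            a, RigidTransform(np.eye(3), np.array([0.3, -0.2, 0.5]))
        )
        assert hausdorff(a, b) == hausdorff(b, a)
        assert hausdorff(a, b, mode="directed") <= hausdorff(a, b)


class TestAngleDefinitions:
    def _axes(self, neck, table_normal=(0, 1, 0), shaft=(0, 0, -1)):
        return FemurAxes(
            head_center=np.array([40.0, 5.0, 450.0]),
            head_radius=23.0,
            neck_axis=np.asarray(neck, float),
            neck_point=np.zeros(3),
            shaft_axis=np.asarray(shaft, float),
            shaft_point=np.zeros(3),
            table_normal=np.asarray(table_normal, float),
            table_point=np.zeros(3),
            condyle_points=np.zeros((2, 3)),
        )

    def test_anteversion_in_plane_is_zero(self):
        axes = self._axes(neck=(1.0, 0.0, 0.0))
        assert femoral_neck_anteversion(axes) == pytest.approx(0.0)

    def test_anteversion_along_normal_is_ninety(self):
        axes = self._axes(neck=(0.0, 1.0, 0.0))
        assert femoral_neck_anteversion(axes) == pytest.approx(90.0)

    def test_projected_convention_differs_predictably(self):
        # neck (a, sin(av), -cos(nsa)) with table normal +y, shaft -z:
        # plane-elevation AV = av; transverse-projection AV = atan2 of
        # the y/x components
        av, nsa = np.radians(5.0), np.radians(135.0)
        sy, cz = np.sin(av), -np.cos(nsa)
        a = np.sqrt(1 - sy**2 - cz**2)
        axes = self._axes(neck=(a, sy, cz))
        axes.condyle_points = np.array(
            [[22.0, -26.0, 0.0], [-22.0, -26.0, 0.0]]
        )
        assert femoral_neck_anteversion(axes) == pytest.approx(5.0)
        expected = np.degrees(np.arctan2(sy, a))
        assert femoral_neck_anteversion(
            axes, projected=True
        ) == pytest.approx(expected, abs=1e-9)

    def test_inclination_perpendicular_axes(self):
        axes = self._axes(neck=(1.0, 0.0, 0.0), shaft=(0.0, 0.0, -1.0))
        assert inclination_angle(axes) == pytest.approx(90.0)

    def test_divergence_three_four_five(self):
        a = self._axes(neck=(1, 0, 0))
        b = self._axes(neck=(1, 0, 0))
        b.head_center = a.head_center + np.array([3.0, 4.0, 0.0])
        assert rotational_center_divergence(a, b) == pytest.approx(5.0)
        assert rotational_center_divergence(a, a) == 0.0

    def test_divergence_requires_common_frame(self):
        a = self._axes(neck=(1, 0, 0))
        b = self._axes(neck=(1, 0, 0))
        b.frame = "scan"
        with pytest.raises(ValueError, match="frame"):
            rotational_center_divergence(a, b)


class TestDeriveAxes:
    def test_closed_loop_against_generator(self, femur, femur_mesh):
        axes = derive_axes(femur_mesh)
        p = femur.params
        assert abs(inclination_angle(axes) - p.nsa) < 2.0
        assert abs(femoral_neck_anteversion(axes) - p.anteversion) < 1.5
        true_len = p.true_max_length()
        measured = max_femoral_length(femur_mesh, axes)
        assert abs(measured - true_len) / true_len < 0.02
        assert (
            np.linalg.norm(axes.head_center - p.head_center) < 2.0
        )

    def test_equivariance_under_recanonicalised_transform(
        self, femur_mesh
    ):
        t = RigidTransform(
            Rotation.from_euler("xyz", [30, -20, 45], degrees=True)
            .as_matrix(),
            np.array([100.0, -50.0, 30.0]),
        )
        # transform out and back: derivation must agree to float precision
        roundtrip = apply_rigid(apply_rigid(femur_mesh, t), t.inverse())
        a = derive_axes(femur_mesh)
        b = derive_axes(roundtrip)
        assert np.allclose(a.head_center, b.head_center, atol=1e-6)
        assert np.allclose(a.neck_axis, b.neck_axis, atol=1e-6)
        assert np.allclose(a.shaft_axis, b.shaft_axis, atol=1e-6)

    def test_hints_override_detection(self, femur_mesh):
        hints = {
            "head_center": [40.0, 5.0, 450.0],
            "head_radius": 21.0,
            "neck_axis": [0.7, 0.1, 0.7],
        }
        axes = derive_axes(femur_mesh, hints=hints)
        assert np.allclose(axes.head_center, hints["head_center"])
        assert axes.head_radius == 21.0
        n = np.asarray(hints["neck_axis"], float)
        assert np.allclose(axes.neck_axis, n / np.linalg.norm(n))


class TestMeasureAll:
    def test_self_measurement_zeros(self, femur_mesh):
        report = measure_all(femur_mesh, femur_mesh)
        assert report.hausdorff_to_reference == 0.0
        assert report.rotational_center_divergence == 0.0
        assert 100.0 < report.inclination_angle < 180.0

    def test_invariant_under_common_rigid_motion(self, femur_mesh):
        axes = derive_axes(femur_mesh)
        base = measure_all(
            femur_mesh, femur_mesh, axes=axes, reference_axes=axes
        )
        t = RigidTransform(
            Rotation.from_euler("zxy", [15, 40, -25], degrees=True)
            .as_matrix(),
            np.array([20.0, 31.0, -7.0]),
        )
        moved = apply_rigid(femur_mesh, t)
        moved_axes = axes.transformed(t)
        rep = measure_all(
            moved, moved, axes=moved_axes, reference_axes=moved_axes
        )
        assert rep.max_femoral_length == pytest.approx(
            base.max_femoral_length, abs=1e-6
        )
        assert rep.femoral_neck_anteversion == pytest.approx(
            base.femoral_neck_anteversion, abs=1e-6
        )
        assert rep.inclination_angle == pytest.approx(
            base.inclination_angle, abs=1e-6
        )

    def test_csv_row_shape(self, femur_mesh):
        report = measure_all(femur_mesh, femur_mesh)
        row = report.csv_row()
        assert len(row.split(",")) == len(
            report.CSV_HEADER.split(",")
        )


class TestHausdorffBound:
    def test_bounded_by_max_vertex_displacement(self, femur_pdm):
        """Symmetric Hausdorff between two model instances never exceeds
        the largest per-vertex displacement between them."""
        rng = np.random.default_rng(2)
        for _ in range(3):
            a = femur_pdm.instance(rng.normal(size=femur_pdm.rank))
            b = femur_pdm.instance(rng.normal(size=femur_pdm.rank))
            bound = np.linalg.norm(a.vertices - b.vertices, axis=1).max()
            assert hausdorff(a, b) <= bound + 1e-9
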