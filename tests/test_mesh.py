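import numpy as np
import pytest

from femurssm.mesh import (
    MeshFormatError,
    RigidTransform,
    TriangleMesh,
    apply_rigid,
    keep_largest_component,
    read_mesh,
    watertight_report,
    write_mesh,
)

from conftest import icosphere, tetrahedron


class TestIO:
    def test_binary_stl_roundtrip_merges_duplicates(self, tmp_path):
        tet = tetrahedron()
        path = tmp_path / "tet.stl"
        write_mesh(tet, path)
        # binary STL: 80-byte header + 4-byte count + 50 bytes per facet
        assert path.stat().st_size == 80 + 4 + 4 * 50
        back = read_mesh(path)
        assert back.n_vertices == 4  # per-facet vertices merged
        assert back.n_faces == 4
        # vertex sets agree within 1e-6 mm (ordering may differ)
        a = np.sort(tet.vertices.round(6).view("f8,f8,f8"), axis=0)
        b = np.sort(back.vertices.round(6).view("f8,f8,f8"), axis=0)
        assert (a == b).all()

    def test_stl_facet_count_field(self, tmp_path):
        sphere = icosphere(3)
        path = tmp_path / "s.stl"
        write_mesh(sphere, path)
        count = int.from_bytes(path.read_bytes()[80:84], "little")
        assert count == sphere.n_faces

    def test_ply_roundtrip_preserves_face_count(self, tmp_path):
        sphere = icosphere(2)
        path = tmp_path / "s.ply"
        write_mesh(sphere, path, format="ply")
        back = read_mesh(path)
        assert back.n_faces == sphere.n_faces
        assert np.allclose(
            np.sort(back.vertices, axis=0),
            np.sort(sphere.vertices, axis=0),
            atol=1e-6,
        )

    def test_ascii_stl_degenerate_facet_dropped(self, tmp_path, caplog):
        body = """solid junk
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 1 0 0
  endloop
endfacet
endsolid junk
"""
        path = tmp_path / "deg.stl"
        path.write_text(body)
        with caplog.at_level("WARNING", logger="femurssm.mesh"):
            mesh = read_mesh(path)
        assert mesh.n_faces == 1
        assert "degenerate" in caplog.text

    def test_missing_and_corrupt_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.stl")
        bad = tmp_path / "bad.stl"
        bad.write_bytes(b"\x00" * 30)
        with pytest.raises(MeshFormatError):
            read_mesh(bad)


class TestInvariants:
    @pytest.mark.parametrize(
        "vertices,faces",
        [
            (np.zeros((2, 3)), [[0, 1, 1]]),  # too few vertices
            (np.zeros((4, 3)), [[0, 1, 9]]),  # index out of range
            (np.zeros((4, 3)), [[0, 1, 1]]),  # repeated vertex in face
            ([[0, 0, np.nan]] * 4, [[0, 1, 2]]),  # non-finite
        ],
    )
    def test_invalid_meshes_rejected(self, vertices, faces):
        with pytest.raises(MeshFormatError):
            TriangleMesh(np.asarray(vertices, float), np.asarray(faces))

    def test_rigid_transform_rejects_scaling_and_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(2.0 * np.eye(3), np.zeros(3))
        reflect = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflect, np.zeros(3))


class TestComponents:
    def test_single_component_unchanged(self):
        tet = tetrahedron()
        out = keep_largest_component(tet)
        assert out.n_faces == tet.n_faces

    def test_keeps_component_with_more_faces(self):
        tet = tetrahedron()
        # second tetrahedron, translated, with one face subdivided (6 faces)
        v2 = tet.vertices + 10.0
        centroid = v2[[1, 2, 3]].mean(axis=0)
        v2 = np.vstack([v2, centroid])
        f2 = np.array(
            [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 4], [2, 3, 4], [3, 1, 4]]
        )
        merged = TriangleMesh(
            np.vstack([tet.vertices, v2]),
            np.vstack([tet.faces, f2 + 4]),
        )
        out = keep_largest_component(merged)
        assert out.n_faces == 6
        assert out.vertices.min() >= 9.0  # the translated copy survived

    def test_face_count_tie_broken_by_area(self):
        small = tetrahedron()
        big = TriangleMesh(small.vertices * 2.0 + 10.0, small.faces)
        merged = TriangleMesh(
            np.vstack([small.vertices, big.vertices]),
            np.vstack([small.faces, big.faces + 4]),
        )
        out = keep_largest_component(merged)
        assert out.vertices.max() > 5.0  # larger-area copy kept


class TestWatertight:
    def test_closed_icosphere(self):
        rep = watertight_report(icosphere(2))
        assert rep == {
            "is_watertight": True,
            "boundary_edges": 0,
            "non_manifold_edges": 0,
        }

    def test_one_face_removed_opens_three_edges(self):
        sphere = icosphere(2)
        holed = TriangleMesh(sphere.vertices, sphere.faces[1:])
        rep = watertight_report(holed)
        assert not rep["is_watertight"]
        assert rep["boundary_edges"] == 3

    def test_inconsistent_winding_flagged(self):
        v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        # both faces traverse the shared edge 1->2 in the same direction
        mesh = TriangleMesh(v, np.array([[0, 1, 2], [3, 1, 2]]))
        rep = watertight_report(mesh)
        assert rep["non_manifold_edges"] >= 1


class TestRigid:
    def test_identity_and_translation(self):
        tet = tetrahedron()
        assert np.allclose(
            apply_rigid(tet, RigidTransform.identity()).vertices,
            tet.vertices,
        )
        t = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        shifted = apply_rigid(tet, t)
        assert np.allclose(
            shifted.centroid() - tet.centroid(), [1.0, 2.0, 3.0]
        )

    def test_composition_matches_sequential_application(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        tet = tetrahedron()
        t1 = RigidTransform(
            Rotation.random(random_state=1).as_matrix(), rng.normal(size=3)
        )
        t2 = RigidTransform(
            Rotation.random(random_state=2).as_matrix(), rng.normal(size=3)
        )
        seq = apply_rigid(apply_rigid(tet, t1), t2)
        comp = apply_rigid(tet, t2.compose(t1))
        assert np.allclose(seq.vertices, comp.vertices, atol=1e-9)

    def test_rigid_preserves_pairwise_distances(self):
        from scipy.spatial.distance import pdist
        from scipy.spatial.transform import Rotation

        sphere = icosphere(2, radius=20.0)
        t = RigidTransform(
            Rotation.random(random_state=7).as_matrix(),
            np.array([5.0, -3.0, 11.0]),
        )
        moved = apply_rigid(sphere, t)
        assert np.allclose(
            pdist(sphere.vertices), pdist(moved.vertices), atol=1e-9
        )

    def test_transform_serialization_roundtrip(self, tmp_path):
        from scipy.spatial.transform import Rotation

        t = RigidTransform(
            Rotation.random(random_state=5).as_matrix(),
            np.array([1.0, 2.0, 3.0]),
        )
        path = tmp_path / "t.txt"
        t.save(path)
        back = RigidTransform.load(path)
        assert np.allclose(back.to_matrix(), t.to_matrix(), atol=1e-12)
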