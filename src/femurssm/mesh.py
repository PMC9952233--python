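"""Triangle-mesh data model, STL/PLY I/O and elementary mesh hygiene.

All coordinates are millimetres in a right-handed frame.  This layer makes
no anatomical assumptions; the canonical femur frame (proximal +z,
anterior +y) is established later, at model-build time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh as _tm

__all__ = [
    "TriangleMesh",
    "RigidTransform",
    "LandmarkSet",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "keep_largest_component",
    "watertight_report",
    "apply_rigid",
]

log = logging.getLogger(__name__)

#: grid used to merge duplicated STL facet vertices (mm)
MERGE_TOL = 1e-9


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or violates invariants."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    faces : (M, 3) int array of vertex indices
    name : optional label carried through the pipeline
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise MeshFormatError(f"vertices must be (N>=3, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 1:
            raise MeshFormatError(f"faces must be (M>=1, 3), got {f.shape}")
        if not np.isfinite(v).all():
            raise MeshFormatError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshFormatError("face index out of range")
        if (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise MeshFormatError("face with repeated vertex")

    # -- convenience ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of per-axis min / max."""
        return np.vstack([self.vertices.min(0), self.vertices.max(0)])

    def bbox_diagonal(self) -> float:
        b = self.bounds()
        return float(np.linalg.norm(b[1] - b[0]))

    def edges_unique(self) -> np.ndarray:
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges_unique()
        d = np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
        )
        return float(d.mean())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(
        cls, mesh: _tm.Trimesh, name: str | None = None
    ) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), name)

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals, dtype=np.float64)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal (RtR != I @ 1e-9)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            self.rotation.T, -self.rotation.T @ self.translation
        )

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path) -> None:
        np.savetxt(path, self.to_matrix(), fmt="%.17g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


@dataclass
class LandmarkSet:
    """K surface points, optionally backed by vertex indices of a mesh."""

    points: np.ndarray
    indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (K, 3)")
        if len(self.points) < 1:
            raise ValueError("need at least one landmark")
        if self.indices is not None:
            self.indices = np.ascontiguousarray(self.indices, dtype=np.int64)
            if len(self.indices) != len(self.points):
                raise ValueError("indices length mismatch")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # STL repeats each vertex once per facet; merge on an exact 1e-9 mm grid
    key = np.round(vertices / MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    return vertices[first], inverse[faces]


def _drop_degenerate_faces(faces: np.ndarray, path: str) -> np.ndarray:
    bad = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if bad.any():
        log.warning(
            "%s: dropped %d degenerate facet(s) with repeated vertices",
            path,
            int(bad.sum()),
        )
        faces = faces[~bad]
    return faces


def read_mesh(path, format: str | None = None) -> TriangleMesh:
    """Read an STL (binary or ASCII) or PLY mesh.

    Per-facet duplicate vertices are merged on a 1e-9 mm grid and facets
    with repeated vertices are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        raw = _tm.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # corrupt file
        size = path.stat().st_size
        raise MeshFormatError(
            f"{path}: unreadable {fmt} file ({size} bytes): {exc}"
        ) from exc
    if isinstance(raw, _tm.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: empty mesh")
        raw = geoms[0]
    v = np.asarray(raw.vertices, dtype=np.float64)
    f = np.asarray(raw.faces, dtype=np.int64)
    if len(v) == 0 or len(f) == 0:
        raise MeshFormatError(f"{path}: empty mesh")
    v, f = _merge_duplicate_vertices(v, f)
    f = _drop_degenerate_faces(f, str(path))
    if len(f) == 0:
        raise MeshFormatError(f"{path}: no valid facets after cleaning")
    return TriangleMesh(v, f, name=path.stem)


def write_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a mesh as binary STL (default) or ascii PLY."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    tm = mesh.to_trimesh()
    if fmt == "stl":
        data = _tm.exchange.stl.export_stl(tm)
    else:
        data = _tm.exchange.ply.export_ply(tm, encoding="ascii")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def _face_areas(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices[mesh.faces]
    return 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )


def keep_largest_component(mesh: TriangleMesh) -> TriangleMesh:
    """Keep the face-connected component with the most faces.

    Connectivity is via shared edges.  Ties on face count are broken by
    larger total surface area; unreferenced vertices are dropped.
    """
    tm = mesh.to_trimesh()
    components = _tm.graph.connected_component_labels(tm.face_adjacency)
    n_comp = components.max() + 1 if len(components) else 1
    if n_comp <= 1:
        return mesh.copy()
    counts = np.bincount(components, minlength=n_comp)
    best = int(np.flatnonzero(counts == counts.max())[0])
    if (counts == counts.max()).sum() > 1:
        areas = _face_areas(mesh)
        tied = np.flatnonzero(counts == counts.max())
        comp_area = np.array(
            [areas[components == c].sum() for c in tied]
        )
        best = int(tied[np.argmax(comp_area)])
        log.info(
            "component face-count tie; keeping larger-area component "
            "(area %.3f mm^2)",
            comp_area.max(),
        )
    keep = components == best
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces], mesh.name)


def watertight_report(mesh: TriangleMesh) -> dict:
    """Edge-manifoldness summary.

    A mesh is watertight when every edge is shared by exactly two faces
    with consistent winding (each undirected edge appears once in each
    direction).
    """
    directed = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(
        und, axis=0, return_inverse=True, return_counts=True
    )
    boundary = int((counts == 1).sum())
    over = int((counts > 2).sum())
    # consistent winding requires each undirected edge once per direction;
    # a repeated *directed* edge means two faces wind the same way
    order = np.lexsort((directed[:, 1], directed[:, 0]))
    ds = directed[order]
    dup = (np.diff(ds, axis=0) == 0).all(axis=1)
    inconsistent = int(dup.sum())
    non_manifold = over + inconsistent
    return {
        "is_watertight": boundary == 0 and non_manifold == 0,
        "boundary_edges": boundary,
        "non_manifold_edges": non_manifold,
    }


def apply_rigid(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Return the mesh with vertices mapped through v -> R v + t."""
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.name)
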