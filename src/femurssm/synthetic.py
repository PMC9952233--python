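"""Procedural femur-like test meshes with known ground truth.

Real cadaveric scans are not redistributable, so the test substrate is a
parametric femur emulator: an implicit-surface union of capsules and
spheres (shaft, neck, head, two condyles, greater trochanter) meshed by
marching cubes.  Every generated mesh carries analytically known
morphometric ground truth (head centre/radius, neck and shaft axes,
neck-shaft angle, anteversion, maximum length), which closes the loop for
testing the measurement and reconstruction code.

Geometry is generated in the canonical anatomical frame used throughout:
proximal +z, anterior +y, medial +x (a left femur).  The posterior
tangents of both condyles and of the greater trochanter are placed at a
common y so the condylar "table" plane of the anteversion definition is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import measure as _sk_measure

from .mesh import LandmarkSet, TriangleMesh
from .morphometrics import FemurAxes

__all__ = [
    "FemurParams",
    "SyntheticFemur",
    "make_femur",
    "sample_population",
    "ablate_proximal",
    "add_vertex_noise",
    "DEFAULT_PRIORS",
]

#: population priors: (mean, sd) per varying parameter, emulating a healthy
#: adult cohort.  Remaining parameters are held at their defaults.
DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "shaft_length": (420.0, 20.0),
    "nsa": (135.0, 3.0),
    "anteversion": (5.0, 1.5),
    "head_radius": (23.0, 1.5),
}


@dataclass(frozen=True)
class FemurParams:
    """Generative parameters of the synthetic femur (mm / degrees)."""

    shaft_length: float = 420.0
    shaft_radius: float = 15.0
    neck_length: float = 65.0
    head_radius: float = 23.0
    nsa: float = 135.0
    anteversion: float = 5.0
    condyle_radius: float = 22.0
    trochanter_offset: float = 18.0
    trochanter_radius: float = 13.0

    def __post_init__(self) -> None:
        for name in (
            "shaft_length",
            "shaft_radius",
            "neck_length",
            "head_radius",
            "condyle_radius",
            "trochanter_offset",
            "trochanter_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 100.0 < self.nsa < 160.0:
            raise ValueError("neck-shaft angle must be in (100, 160) deg")
        if not -10.0 < self.anteversion < 30.0:
            raise ValueError("anteversion must be in (-10, 30) deg")

    # -- analytic geometry --------------------------------------------
    @property
    def neck_direction(self) -> np.ndarray:
        """Unit head-ward neck axis.

        Chosen so the angle with the distal-pointing shaft axis (-z)
        equals ``nsa`` and the elevation out of the condylar table plane
        (normal +y) equals ``anteversion`` exactly.
        """
        av = np.radians(self.anteversion)
        nsa = np.radians(self.nsa)
        cz = -np.cos(nsa)
        sy = np.sin(av)
        sx = np.sqrt(max(1.0 - sy**2 - cz**2, 0.0))
        return np.array([sx, sy, cz])

    @property
    def neck_base(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.shaft_length])

    @property
    def head_center(self) -> np.ndarray:
        return self.neck_base + self.neck_length * self.neck_direction

    @property
    def neck_radius(self) -> float:
        return 0.6 * self.head_radius

    @property
    def table_y(self) -> float:
        """Common posterior-tangent y of condyles and trochanter."""
        return -4.0 - self.condyle_radius

    @property
    def condyle_centers(self) -> np.ndarray:
        cy = self.table_y + self.condyle_radius
        cx = self.condyle_radius
        return np.array([[cx, cy, 0.0], [-cx, cy, 0.0]])

    @property
    def trochanter_center(self) -> np.ndarray:
        r_t = self.trochanter_radius
        return np.array(
            [
                -self.trochanter_offset,
                self.table_y + r_t,
                0.96 * self.shaft_length,
            ]
        )

    def true_max_length(self) -> float:
        """Analytic maximum head-to-condyle distance of the union surface."""
        d = np.linalg.norm(
            self.head_center[None, :] - self.condyle_centers, axis=1
        )
        return float((d + self.head_radius + self.condyle_radius).max())

    def true_axes(self) -> FemurAxes:
        shaft_mid = np.array([0.0, 0.0, 0.5 * self.shaft_length])
        cond = self.condyle_centers.copy()
        cond[:, 1] = self.table_y
        return FemurAxes(
            head_center=self.head_center,
            head_radius=self.head_radius,
            neck_axis=self.neck_direction,
            neck_point=self.neck_base,
            shaft_axis=np.array([0.0, 0.0, -1.0]),
            shaft_point=shaft_mid,
            table_normal=np.array([0.0, 1.0, 0.0]),
            table_point=np.array([0.0, self.table_y, 0.0]),
            condyle_points=cond,
            frame="canonical",
        )


@dataclass
class SyntheticFemur:
    mesh: TriangleMesh
    params: FemurParams
    true_landmarks: LandmarkSet
    true_axes: FemurAxes


def _capsule_sdf(p, a, b, r):
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1) - r


def _sphere_sdf(p, c, r):
    return np.linalg.norm(p - c, axis=1) - r


#: smooth-union blending width (mm); fillets the primitive junctions so
#: the level set has no tangency pinches and the bone has rounded creases
_BLEND_K = 2.0


def _femur_sdf(p: np.ndarray, fp: FemurParams, k: float = _BLEND_K) -> np.ndarray:
    parts = [
        _capsule_sdf(p, np.zeros(3), fp.neck_base, fp.shaft_radius),
        _capsule_sdf(p, fp.neck_base, fp.head_center, fp.neck_radius),
        _sphere_sdf(p, fp.head_center, fp.head_radius),
        _sphere_sdf(p, fp.condyle_centers[0], fp.condyle_radius),
        _sphere_sdf(p, fp.condyle_centers[1], fp.condyle_radius),
        _sphere_sdf(p, fp.trochanter_center, fp.trochanter_radius),
    ]
    # exponential smooth minimum: exact away from junctions (underflow),
    # rounded where primitives meet
    acc = -parts[0] / k
    for d in parts[1:]:
        acc = np.logaddexp(acc, -d / k)
    return -k * acc


def make_femur(
    params: FemurParams | None = None,
    resolution: float = 2.0,
    seed: int = 0,
) -> SyntheticFemur:
    """Mesh the implicit femur at the given voxel pitch (mm).

    The default 2 mm pitch approximates clinical CT slice spacing.  The
    result is watertight and single-component by construction; ground
    truth landmarks and axes come analytically from the parameters.
    """
    fp = params or FemurParams()
    if resolution > fp.shaft_radius / 2:
        raise ValueError(
            "resolution too coarse: must be <= shaft_radius / 2 "
            f"({fp.shaft_radius / 2:.1f} mm)"
        )
    pad = 3.0 * resolution
    pts = np.vstack(
        [
            fp.head_center,
            fp.condyle_centers,
            fp.trochanter_center,
            [[0, 0, 0], [0, 0, fp.shaft_length]],
        ]
    )
    rmax = max(
        fp.head_radius,
        fp.condyle_radius,
        fp.shaft_radius,
        fp.trochanter_radius,
    )
    lo = pts.min(axis=0) - rmax - pad
    hi = pts.max(axis=0) + rmax + pad
    shape = np.ceil((hi - lo) / resolution).astype(int) + 1
    axes = [lo[k] + resolution * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(
        np.meshgrid(*axes, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    vol = _femur_sdf(grid, fp).reshape(shape)
    verts, faces, _, _ = _sk_measure.marching_cubes(
        vol, level=0.0, spacing=(resolution,) * 3
    )
    verts = verts + lo
    # marching cubes can emit coincident vertices and degenerate facets;
    # weld them so downstream topology bookkeeping is clean
    from .mesh import _drop_degenerate_faces, _merge_duplicate_vertices

    verts, faces = _merge_duplicate_vertices(verts, np.ascontiguousarray(faces[:, ::-1]))
    faces = _drop_degenerate_faces(faces, "synthetic femur")
    mesh = TriangleMesh(verts, faces, name=f"synthetic-{seed}")
    lm = LandmarkSet(
        np.vstack(
            [fp.head_center, fp.condyle_centers, fp.trochanter_center]
        )
    )
    return SyntheticFemur(mesh, fp, lm, fp.true_axes())


#: parameters not drawn from priors scale isometrically with shaft length
#: (femur cross-sectional dimensions are strongly allometric in vivo —
#: stature estimation from isolated femoral fragments relies on it)
ALLOMETRIC_FIELDS = (
    "shaft_radius",
    "neck_length",
    "condyle_radius",
    "trochanter_offset",
    "trochanter_radius",
)


def sample_population(
    n: int,
    seed: int = 0,
    priors: dict[str, tuple[float, float]] | None = None,
    resolution: float = 2.0,
    allometry: bool = True,
) -> list[SyntheticFemur]:
    """Draw ``n`` femurs: independent Gaussian priors + allometric scaling.

    The prior-listed parameters are drawn independently.  Parameters not
    covered by a prior are, by default, scaled in proportion to the drawn
    shaft length (isometric allometry), so overall bone size expresses
    itself in the cross-sectional geometry the way it does in real
    skeletal populations; ``allometry=False`` holds them at their
    defaults instead.
    """
    if n < 2:
        raise ValueError("population needs n >= 2")
    priors = dict(DEFAULT_PRIORS if priors is None else priors)
    base = FemurParams()
    valid = set(base.__dataclass_fields__)
    for key, val in priors.items():
        if key not in valid or len(tuple(val)) != 2:
            raise ValueError(f"invalid prior spec for {key!r}: {val!r}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        draw = {
            key: float(rng.normal(mu, sd)) for key, (mu, sd) in priors.items()
        }
        if allometry:
            scale = (
                draw.get("shaft_length", base.shaft_length)
                / FemurParams.shaft_length
            )
            for name in ALLOMETRIC_FIELDS:
                if name not in draw:
                    draw[name] = getattr(base, name) * scale
        fem = make_femur(
            replace(base, **draw), resolution=resolution, seed=seed
        )
        fem.mesh.name = f"specimen-{i:03d}"
        out.append(fem)
    return out


def ablate_proximal(
    mesh: TriangleMesh,
    cut_fraction: float,
    plane_normal: np.ndarray | None = None,
) -> TriangleMesh:
    """Remove the proximal ``cut_fraction`` of the mesh along a cut plane.

    The cut plane sits at the given fraction from the proximal end of the
    bounding box measured along ``plane_normal`` (default +z).  Faces with
    any vertex on the proximal side are dropped, leaving an open boundary,
    like a resected specimen.
    """
    if not 0.0 < cut_fraction < 1.0:
        if cut_fraction == 0.0:
            return mesh.copy()
        raise ValueError("cut_fraction must be in (0, 1)")
    n = np.array([0.0, 0.0, 1.0]) if plane_normal is None else np.asarray(
        plane_normal, dtype=np.float64
    )
    n = n / np.linalg.norm(n)
    s = mesh.vertices @ n
    thr = s.min() + (1.0 - cut_fraction) * (s.max() - s.min())
    drop = (s[mesh.faces] > thr).any(axis=1)
    keep_faces = mesh.faces[~drop]
    if len(keep_faces) == 0:
        raise ValueError("cut removes the entire mesh")
    used = np.unique(keep_faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(
        mesh.vertices[used], remap[keep_faces], name=mesh.name
    )


def add_vertex_noise(
    mesh: TriangleMesh, sigma: float, seed: int = 0
) -> TriangleMesh:
    """Gaussian displacement along vertex normals (CT/segmentation noise)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    normals = mesh.vertex_normals()
    disp = rng.normal(0.0, sigma, size=mesh.n_vertices)
    return TriangleMesh(
        mesh.vertices + disp[:, None] * normals, mesh.faces.copy(), mesh.name
    )
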