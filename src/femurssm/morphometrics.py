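"""Quantitative femur morphometry.

Five measurements per shape: maximum femoral length, Hausdorff distance to
a reference shape, femoral neck anteversion, rotational-centre divergence,
and the angle of inclination (neck-shaft angle, NSA).

Definitions
-----------
* Maximum femoral length — largest Euclidean distance between a femoral
  head point and a femoral condyle point.
* Hausdorff distance — worst-case vertex-to-surface distance, symmetric by
  default.
* Anteversion — angle between the head/neck longitudinal axis and the
  axial "table" plane through the most posterior points of the two
  condyles and of the greater trochanter.
* Rotational-centre divergence — distance between the head's centre of
  rotation (least-squares sphere centre) and the reference shape's.
* Inclination (NSA) — angle between the head/neck axis and the shaft
  axis, on the obtuse convention (healthy adult values ≈ 120–145°).

Automatic landmarking assumes the canonical anatomical frame used by the
model build: proximal +z, anterior +y, medial +x.  Every window fraction
is configurable, and explicit landmark hints override detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .mesh import RigidTransform, TriangleMesh
from .proximity import SurfaceQuery

__all__ = [
    "FemurAxes",
    "MorphometricsReport",
    "AxisWindows",
    "fit_sphere",
    "derive_axes",
    "max_femoral_length",
    "hausdorff",
    "femoral_neck_anteversion",
    "rotational_center_divergence",
    "inclination_angle",
    "measure_all",
]

log = logging.getLogger(__name__)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis vector")
    return v / n


@dataclass
class FemurAxes:
    """Derived anatomical axes and landmarks of one femur."""

    head_center: np.ndarray
    head_radius: float
    neck_axis: np.ndarray  # unit, head-ward
    neck_point: np.ndarray
    shaft_axis: np.ndarray  # unit, distal-ward
    shaft_point: np.ndarray
    table_normal: np.ndarray  # unit, anterior-ward
    table_point: np.ndarray
    condyle_points: np.ndarray  # (2, 3): most posterior condyle points
    frame: str = "canonical"

    def __post_init__(self) -> None:
        for name in ("neck_axis", "shaft_axis", "table_normal"):
            setattr(
                self, name, _unit(np.asarray(getattr(self, name), float))
            )
        for name in (
            "head_center",
            "neck_point",
            "shaft_point",
            "table_point",
        ):
            setattr(self, name, np.asarray(getattr(self, name), float))
        self.condyle_points = np.asarray(self.condyle_points, float)
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")

    def transformed(self, t: RigidTransform) -> "FemurAxes":
        R = t.rotation
        return replace(
            self,
            head_center=t.apply(self.head_center),
            neck_axis=R @ self.neck_axis,
            neck_point=t.apply(self.neck_point),
            shaft_axis=R @ self.shaft_axis,
            shaft_point=t.apply(self.shaft_point),
            table_normal=R @ self.table_normal,
            table_point=t.apply(self.table_point),
            condyle_points=t.apply(self.condyle_points),
        )


@dataclass
class MorphometricsReport:
    specimen: str
    max_femoral_length: float
    hausdorff_to_reference: float
    femoral_neck_anteversion: float
    rotational_center_divergence: float
    inclination_angle: float
    frame: str = "canonical"

    def __post_init__(self) -> None:
        vals = [
            self.max_femoral_length,
            self.hausdorff_to_reference,
            self.femoral_neck_anteversion,
            self.rotational_center_divergence,
            self.inclination_angle,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("measurements must be non-negative")
        for ang in (self.femoral_neck_anteversion, self.inclination_angle):
            if not 0 <= ang < 180:
                raise ValueError("angles must lie in [0, 180)")

    CSV_HEADER = (
        "specimen,max_femoral_length_mm,hausdorff_mm,anteversion_deg,"
        "rotational_center_divergence_mm,inclination_deg,frame"
    )

    def csv_row(self) -> str:
        return (
            f"{self.specimen},{self.max_femoral_length:.3f},"
            f"{self.hausdorff_to_reference:.3f},"
            f"{self.femoral_neck_anteversion:.3f},"
            f"{self.rotational_center_divergence:.3f},"
            f"{self.inclination_angle:.3f},{self.frame}"
        )


@dataclass(frozen=True)
class AxisWindows:
    """Z-window fractions for automatic landmark detection."""

    shaft_lo: float = 0.25
    shaft_hi: float = 0.75
    head: float = 0.15
    condyle: float = 0.15
    trochanter: float = 0.25


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def fit_sphere(points: np.ndarray) -> dict:
    """Algebraic least-squares sphere fit.

    Solves the linear system 2 p·c + (r^2 - |c|^2) = |p|^2 for the centre
    and radius.  Raises on coplanar/degenerate input.
    """
    p = np.asarray(points, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise ValueError("need at least 4 points of shape (K, 3)")
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError(
            f"sphere fit is rank-deficient (rank {rank}); points coplanar?"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    rms = float(
        np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - radius) ** 2))
    )
    return {"center": center, "radius": radius, "rms": rms}


def _fit_head_sphere(
    points: np.ndarray, cap_height: float = 18.0, iters: int = 10
) -> dict:
    """Femoral-head sphere fit seeded from the proximal apex.

    The head is the most proximal structure in the canonical frame, so a
    cap of vertices just below the topmost point lies on the head alone.
    The algebraic fit on that cap is then refined by iteratively re-fitting
    on the shell of points consistent with the current sphere.
    """
    z = points[:, 2]
    cap = points[z > z.max() - cap_height]
    if len(cap) < 10:
        raise ValueError("proximal apex cap too sparse for head fit")
    fit = fit_sphere(cap)
    for _ in range(iters):
        d = np.linalg.norm(points - fit["center"], axis=1)
        keep = np.abs(d - fit["radius"]) < 2.0
        if keep.sum() < 10:
            break
        new = fit_sphere(points[keep])
        converged = (
            np.linalg.norm(new["center"] - fit["center"]) < 1e-9
            and abs(new["radius"] - fit["radius"]) < 1e-9
        )
        fit = new
        if converged:
            break
    return fit


def hausdorff(
    a: TriangleMesh, b: TriangleMesh, mode: str = "symmetric"
) -> float:
    """Worst-case vertex-to-surface distance between two meshes.

    ``directed`` gives max over a's vertices of the exact point-to-triangle
    distance to b's surface; ``symmetric`` (default) takes the larger of
    the two directed values.
    """
    if mode not in ("directed", "symmetric"):
        raise ValueError("mode must be 'directed' or 'symmetric'")
    d_ab = float(SurfaceQuery(b).distance(a.vertices).max())
    if mode == "directed":
        return d_ab
    d_ba = float(SurfaceQuery(a).distance(b.vertices).max())
    return max(d_ab, d_ba)


# ---------------------------------------------------------------------------
# axis derivation
# ---------------------------------------------------------------------------


def derive_axes(
    mesh: TriangleMesh,
    hints: dict | None = None,
    windows: AxisWindows | None = None,
    frame: str = "canonical",
) -> FemurAxes:
    """Automatic anatomical axis/landmark detection in the canonical frame.

    Shaft axis: dominant principal direction of the mid-shaft vertex band.
    Head: trimmed least-squares sphere over the proximal z-window.  Neck
    axis: line through the head centre and centroids of minimal
    cross-section rings of the neck.  Condyle / trochanter posterior
    points: minimal-y vertices in their z-windows.  ``hints`` entries
    (``head_center``, ``head_radius``, ``neck_axis``, ``condyle_points``,
    ``trochanter_point``) override detection.
    """
    w = windows or AxisWindows()
    hints = hints or {}
    v = mesh.vertices
    z = v[:, 2]
    zmin, zmax = z.min(), z.max()
    zr = zmax - zmin

    # ---- shaft ----
    # include face centroids so coarse axial tessellation cannot empty
    # the band
    cent = v[mesh.faces].mean(axis=1)
    zc = cent[:, 2]
    band = np.vstack(
        [
            v[(z >= zmin + w.shaft_lo * zr) & (z <= zmin + w.shaft_hi * zr)],
            cent[
                (zc >= zmin + w.shaft_lo * zr)
                & (zc <= zmin + w.shaft_hi * zr)
            ],
        ]
    )
    if len(band) < 10:
        raise ValueError("shaft window is empty; provide landmark hints")
    bc = band.mean(axis=0)
    _, _, vt = np.linalg.svd(band - bc, full_matrices=False)
    shaft_dir = vt[0]
    if shaft_dir[2] > 0:  # orient distal-ward (-z)
        shaft_dir = -shaft_dir

    # ---- head ----
    if "head_center" in hints:
        head_center = np.asarray(hints["head_center"], float)
        head_radius = float(hints.get("head_radius", 23.0))
    else:
        prox = v[z >= zmax - w.head * zr]
        if len(prox) < 30:
            raise ValueError("head window is empty; provide landmark hints")
        fit = _fit_head_sphere(prox)
        head_center, head_radius = fit["center"], fit["radius"]
    head_mask = np.linalg.norm(v - head_center, axis=1) <= 1.05 * head_radius

    # ---- neck ----
    if "neck_axis" in hints:
        neck_dir = _unit(np.asarray(hints["neck_axis"], float))
        neck_point = head_center - head_radius * neck_dir
    else:
        neck_dir, neck_point = _detect_neck_axis(
            v, head_center, head_radius, bc, shaft_dir
        )

    # ---- posterior landmarks ----
    axis_x = v @ np.array([1.0, 0, 0])
    shaft_x = bc[0]
    medial_sign = np.sign(head_center[0] - shaft_x) or 1.0
    if "condyle_points" in hints:
        condyles = np.asarray(hints["condyle_points"], float)
    else:
        dist_mask = z <= zmin + w.condyle * zr
        if not dist_mask.any():
            raise ValueError("condyle window empty; provide hints")
        med = dist_mask & ((axis_x - shaft_x) * medial_sign > 0)
        lat = dist_mask & ~((axis_x - shaft_x) * medial_sign > 0)
        if not med.any() or not lat.any():
            raise ValueError("condyle split failed; provide hints")
        condyles = np.vstack(
            [
                v[med][np.argmin(v[med][:, 1])],
                v[lat][np.argmin(v[lat][:, 1])],
            ]
        )
    if "trochanter_point" in hints:
        troch = np.asarray(hints["trochanter_point"], float)
    else:
        prox_mask = (z >= zmax - w.trochanter * zr) & ~head_mask
        # exclude the neck tube as well
        to_axis = v - neck_point
        along = to_axis @ neck_dir
        radial = np.linalg.norm(
            to_axis - along[:, None] * neck_dir[None, :], axis=1
        )
        prox_mask &= ~((radial < 1.2 * 0.75 * head_radius) & (along > 0))
        if not prox_mask.any():
            raise ValueError("trochanter window empty; provide hints")
        troch = v[prox_mask][np.argmin(v[prox_mask][:, 1])]

    n = np.cross(condyles[1] - condyles[0], troch - condyles[0])
    if np.linalg.norm(n) < 1e-9:
        raise ValueError("degenerate table plane (collinear landmarks)")
    n = _unit(n)
    if n @ (v.mean(axis=0) - condyles[0]) < 0:
        n = -n  # orient anterior-ward (towards the bone mass)

    return FemurAxes(
        head_center=head_center,
        head_radius=float(head_radius),
        neck_axis=neck_dir,
        neck_point=neck_point,
        shaft_axis=shaft_dir,
        shaft_point=bc,
        table_normal=n,
        table_point=condyles[0],
        condyle_points=condyles,
        frame=frame,
    )


def _circle_fit_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit; well-posed on partial arcs."""
    A = np.hstack([2.0 * xy, np.ones((len(xy), 1))])
    b = (xy**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate ring for circle fit")
    c = sol[:2]
    r2 = sol[2] + c @ c
    if r2 <= 0:
        raise ValueError("circle fit produced non-positive radius")
    return c, float(np.sqrt(r2))


def _detect_neck_axis(
    v: np.ndarray,
    head_center: np.ndarray,
    head_radius: float,
    shaft_point: np.ndarray,
    shaft_dir: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Neck axis from circle fits to neck cross-sections.

    The axis is anchored at the head centre (known to sub-millimetre
    accuracy from the sphere fit).  Cross-section slabs along a current
    direction estimate are projected onto the perpendicular plane and a
    circle is fitted to each — unlike slab centroids, a circle centre is
    unbiased even when the ring is partial (occluded by the
    shaft/trochanter junction).  Points close to the shaft surface are
    excluded using the already-derived shaft axis.
    """
    # seed direction: from the collar of vertices just outside the head
    d_head = np.linalg.norm(v - head_center, axis=1)
    collar = v[(d_head > 1.05 * head_radius) & (d_head < 1.6 * head_radius)]
    if len(collar) < 10:
        raise ValueError("could not find neck collar; provide hints")
    direction = _unit(head_center - collar.mean(axis=0))

    u_s = v - shaft_point
    dist_shaft = np.linalg.norm(
        u_s - np.outer(u_s @ shaft_dir, shaft_dir), axis=1
    )
    mid = np.abs((v[:, 2] - v[:, 2].min()) / np.ptp(v[:, 2]) - 0.5) < 0.25
    r_shaft = float(np.median(dist_shaft[mid]))

    u = v - head_center
    centers_kept: np.ndarray | None = None
    for _ in range(5):
        along = u @ (-direction)
        e1 = np.cross(direction, [0.0, 0.0, 1.0])
        n1 = np.linalg.norm(e1)
        if n1 < 1e-6:  # neck almost axial: any perpendicular basis works
            e1 = np.cross(direction, [1.0, 0.0, 0.0])
            n1 = np.linalg.norm(e1)
        e1 /= n1
        e2 = np.cross(direction, e1)
        centers = []
        for s in np.arange(1.05, 2.2, 0.12) * head_radius:
            sel = (
                (np.abs(along - s) < 0.07 * head_radius)
                & (d_head < 2.4 * head_radius)
                & (dist_shaft > r_shaft + 4.0)
            )
            if sel.sum() < 10:
                continue
            xy = np.stack([u[sel] @ e1, u[sel] @ e2], axis=1)
            try:
                c2, rr = _circle_fit_2d(xy)
                resid = np.abs(np.linalg.norm(xy - c2, axis=1) - rr)
                keep = resid < 3.0 * np.median(resid) + 0.5
                if keep.sum() < 10:
                    continue
                c2, rr = _circle_fit_2d(xy[keep])
            except ValueError:
                continue
            if not 0.3 * head_radius < rr < 1.1 * head_radius:
                continue
            centers.append(
                head_center + c2[0] * e1 + c2[1] * e2 - s * direction
            )
        if len(centers) < 2:
            break
        pts = np.vstack([centers, head_center])
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        new_dir = vt[0]
        if new_dir @ direction < 0:
            new_dir = -new_dir
        direction = new_dir
        centers_kept = np.asarray(centers)
    if centers_kept is None:
        raise ValueError("could not track neck cross-sections; provide hints")
    return direction, centers_kept.mean(axis=0)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def max_femoral_length(mesh: TriangleMesh, axes: FemurAxes) -> float:
    """Max distance between head-region and condylar-region vertices.

    Regions come from the supplied axes (head sphere; distal 15% along
    the shaft axis), so the measurement is equivariant under rigid
    motion of mesh + axes together.
    """
    v = mesh.vertices
    s = v @ axes.shaft_axis  # distal-ward coordinate
    smin, smax = s.min(), s.max()
    head = v[
        np.linalg.norm(v - axes.head_center, axis=1)
        <= 1.05 * axes.head_radius
    ]
    cond = v[s >= smax - 0.15 * (smax - smin)]
    if len(head) == 0 or len(cond) == 0:
        raise ValueError("empty head or condyle region")
    # reduce both regions to their convex extremes for an exact max
    d = np.linalg.norm(
        head[:, None, :] - cond[None, :, :], axis=2
    )
    return float(d.max())


def femoral_neck_anteversion(axes: FemurAxes, projected: bool = False) -> float:
    """Angle (deg) between the neck axis and the condylar table plane.

    Default: the literal axis-to-plane angle (90 deg minus the angle to
    the plane normal), in [0, 90].  ``projected`` instead measures the
    radiological convention: neck axis and posterior condylar line are
    both projected into the transverse plane (perpendicular to the
    shaft) and the angle between the projections is reported.
    """
    if projected:
        n_t = axes.shaft_axis
        v = axes.neck_axis - (axes.neck_axis @ n_t) * n_t
        c = axes.condyle_points[0] - axes.condyle_points[1]
        c = c - (c @ n_t) * n_t
        nv, nc = np.linalg.norm(v), np.linalg.norm(c)
        if nv < 1e-12 or nc < 1e-12:
            raise ValueError(
                "degenerate projection for the transverse-plane convention"
            )
        cosang = abs(float(v @ c) / (nv * nc))
        return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    s = abs(float(axes.neck_axis @ axes.table_normal))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def rotational_center_divergence(
    subject_axes: FemurAxes, reference_axes: FemurAxes
) -> float:
    """Distance (mm) between subject and reference head centres."""
    if subject_axes.frame != reference_axes.frame:
        raise ValueError(
            f"axes frames differ: {subject_axes.frame!r} vs "
            f"{reference_axes.frame!r}"
        )
    return float(
        np.linalg.norm(subject_axes.head_center - reference_axes.head_center)
    )


def inclination_angle(axes: FemurAxes) -> float:
    """Neck-shaft angle (deg): neck axis (head-ward) vs shaft (distal-ward)."""
    c = float(np.clip(axes.neck_axis @ axes.shaft_axis, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def measure_all(
    mesh: TriangleMesh,
    reference_mean: TriangleMesh,
    axes: FemurAxes | None = None,
    reference_axes: FemurAxes | None = None,
    hints: dict | None = None,
) -> MorphometricsReport:
    """All five measurements of one shape against a reference mean."""
    axes = axes or derive_axes(mesh, hints=hints)
    reference_axes = reference_axes or derive_axes(reference_mean)
    return MorphometricsReport(
        specimen=mesh.name or "unnamed",
        max_femoral_length=max_femoral_length(mesh, axes),
        hausdorff_to_reference=hausdorff(mesh, reference_mean),
        femoral_neck_anteversion=femoral_neck_anteversion(axes),
        rotational_center_divergence=rotational_center_divergence(
            axes, reference_axes
        ),
        inclination_angle=inclination_angle(axes),
        frame=axes.frame,
    )
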