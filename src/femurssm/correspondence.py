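"""Dense correspondence by Gaussian-process non-rigid registration.

A zero-mean Gaussian process over deformation fields of a reference mesh,
with the isotropic matrix-valued squared-exponential kernel

    k(p, q) = s^2 * exp(-||p - q||^2 / (2 l^2)) * I3,

defines the family of admissible smooth deformations.  The kernel is the
"symmetric Gaussian" of GP morphable models: the same scalar kernel acts
on each coordinate and it is symmetric in its arguments.  A low-rank
(Nystrom) eigenbasis of the kernel makes registration a small linear
regression: iteratively, surface samples of the deformed reference are
matched to their closest points on the target and the deformation
coefficients are updated by GP posterior mean, with the observation noise
annealed so early (wrong) matches cannot overfit.

Because every registered specimen is the same deformed reference, all
outputs share one topology — the prerequisite for building the PCA shape
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import farthest_point_sample
from .mesh import TriangleMesh
from .proximity import SurfaceQuery

__all__ = [
    "LowRankDeformationModel",
    "CorrespondedMesh",
    "gaussian_kernel_basis",
    "build_deformation_model",
    "nonrigid_register",
    "RegistrationResult",
]

log = logging.getLogger(__name__)


def _orient_columns(basis: np.ndarray) -> np.ndarray:
    """Fix eigenvector signs: largest-|entry| of each column positive."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def gaussian_kernel_basis(
    points: np.ndarray,
    s: float,
    lengthscale: float,
    rank: int,
    n_inducing: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank orthonormal basis of the matrix-valued Gaussian kernel.

    Nystrom approximation on ``n_inducing`` farthest-point-sampled
    inducing points, exploiting the tensor structure: the 3N x 3N kernel
    matrix is G (x) I3 for the scalar kernel matrix G, so each scalar
    eigenfunction yields three vector-field basis columns (one per
    coordinate) with equal variance.

    Returns (basis (3N, r), variances (r,)) with orthonormal columns and
    variances sorted descending; r <= rank.
    """
    if s <= 0 or lengthscale <= 0:
        raise ValueError("kernel scale and lengthscale must be positive")
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    m = min(n_inducing, n)
    if rank > 3 * m:
        raise ValueError(f"rank {rank} exceeds 3 * n_inducing = {3 * m}")
    # deterministic farthest-point inducing set
    dummy_faces = np.array([[0, 1, 2]])
    sample = farthest_point_sample(
        TriangleMesh(pts, dummy_faces), m, seed=seed
    )
    ind = pts[sample.indices]

    def scalar_kernel(a, b):
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        return np.exp(-0.5 * d2 / lengthscale**2)

    G_mm = scalar_kernel(ind, ind)
    G_nm = scalar_kernel(pts, ind)
    evals, evecs = np.linalg.eigh(G_mm)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(1e-12 * evals[0], 1e-12)
    q_scalar = min(int(np.ceil(rank / 3)), int(keep.sum()))
    if 3 * q_scalar < rank:
        log.warning(
            "kernel rank deficient: returning rank %d < requested %d",
            3 * q_scalar,
            rank,
        )
    evals = evals[:q_scalar]
    evecs = evecs[:, :q_scalar]
    # Nystrom extension to all points, then re-orthonormalise exactly:
    # with ext = G_nm U L^-1 the approximation is G ~= ext L ext^T
    # (= G_nm G_mm^-1 G_mn); QR-factor ext and eigen-decompose the small
    # projected covariance, so all extension scaling lands in R
    ext = G_nm @ (evecs / evals)  # (n, q)
    W, R = np.linalg.qr(ext)
    M = R @ np.diag(evals) @ R.T
    lam_s, U = np.linalg.eigh(M)
    order = np.argsort(lam_s)[::-1]
    lam_s, U = lam_s[order], U[:, order]
    W = _orient_columns(W @ U)
    lam_s = np.maximum(lam_s, 0.0) * s**2

    # expand scalar modes to 3-D vector fields: w (x) e_a, interleaved
    # component layout (x0 y0 z0 x1 y1 z1 ...)
    r_out = min(rank, 3 * q_scalar)
    basis = np.zeros((3 * n, r_out))
    variances = np.empty(r_out)
    col = 0
    for j in range(q_scalar):
        for a in range(3):
            if col >= r_out:
                break
            basis[a::3, col] = W[:, j]
            variances[col] = lam_s[j]
            col += 1
    return basis, variances


@dataclass
class LowRankDeformationModel:
    """Low-rank GP over deformations of a reference mesh."""

    reference: TriangleMesh
    basis: np.ndarray  # (3N, r), orthonormal columns
    variances: np.ndarray  # (r,), descending, > 0
    kernel_params: dict  # {"s": mm, "lengthscale": mm}

    def __post_init__(self) -> None:
        r = self.basis.shape[1]
        if self.basis.shape[0] != 3 * self.reference.n_vertices:
            raise ValueError("basis rows != 3 * reference vertex count")
        if len(self.variances) != r:
            raise ValueError("variances length != basis rank")
        if (np.diff(self.variances) > 1e-9).any():
            raise ValueError("variances must be sorted descending")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(r), atol=1e-8):
            raise ValueError("basis columns are not orthonormal (1e-8)")

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def deform(self, alpha: np.ndarray) -> np.ndarray:
        """Vertex positions of the reference deformed by coefficients
        ``alpha`` (standard-deviation units per mode)."""
        disp = self.basis @ (np.sqrt(self.variances) * alpha)
        return self.reference.vertices + disp.reshape(-1, 3)


class CorrespondedMesh(TriangleMesh):
    """A mesh carrying the reference topology of a deformation model."""

    def __init__(self, vertices, reference: TriangleMesh, name=None):
        super().__init__(
            np.asarray(vertices), reference.faces.copy(), name=name
        )
        if self.n_vertices != reference.n_vertices:
            raise ValueError("vertex count differs from reference")


def build_deformation_model(
    reference: TriangleMesh,
    s: float = 10.0,
    lengthscale: float | None = None,
    rank: int = 150,
    n_inducing: int = 500,
    seed: int = 0,
) -> LowRankDeformationModel:
    """Low-rank Gaussian-kernel deformation prior on a reference mesh.

    ``lengthscale`` defaults to a quarter of the reference bounding-box
    diagonal — long enough that the leading modes are near-global
    (translation-like) deformations, short enough to bend the neck and
    shaft independently.
    """
    if lengthscale is None:
        lengthscale = 0.25 * reference.bbox_diagonal()
    basis, variances = gaussian_kernel_basis(
        reference.vertices, s, lengthscale, rank, n_inducing, seed=seed
    )
    return LowRankDeformationModel(
        reference=reference,
        basis=basis,
        variances=variances,
        kernel_params={"s": float(s), "lengthscale": float(lengthscale)},
    )


@dataclass
class RegistrationResult:
    mesh: CorrespondedMesh
    coefficients: np.ndarray
    residuals: list  # mean sample-to-target distance per iteration
    iterations: int


def nonrigid_register(
    model: LowRankDeformationModel,
    target: TriangleMesh,
    n_points: int = 1000,
    max_iter: int = 100,
    sigma2_start: float = 1.0,
    sigma2_floor: float = 0.1,
    anneal: float = 0.95,
    seed: int = 0,
    resample: bool = False,
    tol: float = 1e-3,
    symmetric: bool = True,
    full_output: bool = False,
):
    """Deform the model reference onto a pre-aligned target mesh.

    Each iteration: (a) farthest-point sample ``n_points`` surface points
    of the currently deformed reference (fixed after the first iteration
    unless ``resample``); (b) find their exact closest points on the
    target surface; (c) update the deformation coefficients by GP
    posterior mean under observation noise ``sigma2``; (d) anneal sigma2
    towards ``sigma2_floor``.  Stops when the mean vertex displacement
    changes by less than ``tol`` mm.

    With ``symmetric`` (default) an equal number of target samples is
    matched back to the deformed reference each iteration; without the
    reverse direction, target features the reference never reaches (a
    trochanter, a condyle lobe) exert no pull and the registration can
    converge with them unexplained.

    Returns the deformed reference as a :class:`CorrespondedMesh`
    (or a :class:`RegistrationResult` when ``full_output``).
    """
    ref = model.reference
    surf = SurfaceQuery(target)
    sqrt_lam = np.sqrt(model.variances)
    alpha = np.zeros(model.rank)
    sigma2 = float(sigma2_start)
    diameter = ref.bbox_diagonal()
    residuals: list[float] = []
    sample_idx: np.ndarray | None = None
    target_pts: np.ndarray | None = None
    prev_vertices = ref.vertices.copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        deformed = model.deform(alpha)
        if sample_idx is None or resample:
            sample_idx = farthest_point_sample(
                TriangleMesh(deformed, ref.faces), n_points, seed=seed
            ).indices
        pts = deformed[sample_idx]
        dists, closest, _ = surf.query(pts)
        residuals.append(float(dists.mean()))
        obs_idx = sample_idx
        obs_pos = closest
        if symmetric:
            if target_pts is None:
                target_pts = farthest_point_sample(
                    target, min(n_points, target.n_vertices), seed=seed
                ).points
            dsurf = SurfaceQuery(TriangleMesh(deformed, ref.faces))
            _, _, tri_ids = dsurf.query(target_pts)
            # attribute each target sample to the nearest vertex of its
            # closest deformed-reference triangle
            cand = ref.faces[tri_ids]  # (k, 3) vertex ids
            dd = np.linalg.norm(
                deformed[cand] - target_pts[:, None, :], axis=2
            )
            rev_idx = cand[np.arange(len(cand)), np.argmin(dd, axis=1)]
            obs_idx = np.concatenate([obs_idx, rev_idx])
            obs_pos = np.vstack([obs_pos, target_pts])
        # GP regression of coefficients on the pseudo-correspondences:
        # rows of the scaled basis at the observed vertices
        rows = np.stack(
            [3 * obs_idx, 3 * obs_idx + 1, 3 * obs_idx + 2], axis=1
        ).ravel()
        Q = model.basis[rows] * sqrt_lam
        y = (obs_pos - ref.vertices[obs_idx]).ravel()
        A = np.eye(model.rank) + (Q.T @ Q) / sigma2
        alpha = np.linalg.solve(A, Q.T @ y / sigma2)
        new_vertices = model.deform(alpha)
        step = float(
            np.mean(np.linalg.norm(new_vertices - prev_vertices, axis=1))
        )
        disp = float(
            np.mean(np.linalg.norm(new_vertices - ref.vertices, axis=1))
        )
        if disp > 10.0 * diameter:
            raise RuntimeError(
                f"registration diverged: mean displacement {disp:.1f} mm "
                f"exceeds 10x reference diameter ({diameter:.1f} mm)"
            )
        prev_vertices = new_vertices
        sigma2 = max(sigma2 * anneal, sigma2_floor)
        if step < tol:
            break
    # reprojection: snap each deformed vertex to its exact closest point
    # on the target surface.  The GP fit leaves sub-millimetre
    # normal-direction residuals; left in place they become spurious
    # "noise modes" in the PCA that downstream fitting can exploit.
    # Tangential correspondence is untouched (the move is the shortest
    # one), and a cap guards against snapping across thin structures.
    dists, snapped, _ = surf.query(prev_vertices)
    cap = 0.05 * diameter
    ok = dists < cap
    final = prev_vertices.copy()
    final[ok] = snapped[ok]
    out = CorrespondedMesh(final, ref, name=target.name)
    if full_output:
        return RegistrationResult(out, alpha, residuals, iterations)
    return out
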