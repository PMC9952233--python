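"""Statistical reconstruction of missing anatomy by GP posterior regression.

Given a (typically augmented) shape model and a damaged specimen, the
intact surface supplies partial observations of model vertices; the
posterior over shape coefficients is Gaussian with

    Sigma = (I + Q^T Q / sigma^2)^-1,
    m_alpha = Sigma Q^T (y - mu_obs) / sigma^2,

where Q holds the rows of Phi diag(sqrt(lambda)) at observed vertices.
The posterior mean completes the femur; the leading posterior mode spans
the remaining uncertainty, from which the seven +/-k SD reconstruction
variants (k = 0..3) are generated.  ``stitch_reconstruction`` replaces
model geometry with the measured surface wherever the specimen is intact,
blending across the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import TriangleMesh
from .proximity import SurfaceQuery
from .ssm import PointDistributionModel

__all__ = [
    "PartialObservations",
    "PosteriorModel",
    "establish_partial_correspondence",
    "posterior",
    "reconstruct_variants",
    "stitch_reconstruction",
    "DEFAULT_VARIANT_LEVELS",
]

log = logging.getLogger(__name__)

DEFAULT_VARIANT_LEVELS = (-3, -2, -1, 0, 1, 2, 3)


@dataclass
class PartialObservations:
    """Observed 3-D positions of a subset of model vertices.

    ``normals``, when present, are the observed-surface unit normals at
    the matched points; they allow the posterior to constrain only the
    normal direction (point-to-plane), which closest-point matching
    actually measures.
    """

    indices: np.ndarray  # (m,) model vertex indices, unique
    points: np.ndarray  # (m, 3) observed positions, mm
    sigma2: float  # observation noise variance, mm^2
    normals: np.ndarray | None = None  # (m, 3) unit normals at matches

    def __post_init__(self) -> None:
        self.indices = np.ascontiguousarray(self.indices, dtype=np.int64)
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if len(self.indices) != len(self.points):
            raise ValueError("indices and points length mismatch")
        if len(self.indices) < 3:
            raise ValueError("need at least 3 observations")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("observation indices must be unique")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(
                self.normals, dtype=np.float64
            )
            if self.normals.shape != self.points.shape:
                raise ValueError("normals shape mismatch")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class PosteriorModel:
    """Posterior shape model plus the intact/reconstructed vertex labels."""

    model: PointDistributionModel
    intact: np.ndarray  # (N,) bool; True where the specimen was observed
    observations: PartialObservations

    def __post_init__(self) -> None:
        if len(self.intact) != self.model.n_vertices:
            raise ValueError("label length != model vertex count")

    def mean_mesh(self) -> TriangleMesh:
        m = self.model.mean_mesh()
        m.name = "posterior-mean"
        return m


def establish_partial_correspondence(
    pdm: PointDistributionModel,
    partial: TriangleMesh,
    accept_dist: float = 5.0,
    sigma2: float = 1.0,
    seed: int = 0,
    from_vertices: np.ndarray | None = None,
) -> PartialObservations:
    """Match model-mean vertices to the intact surface of a specimen.

    The partial mesh must already be rigidly aligned to the model frame
    (e.g. ``icp_rigid`` against the model mean).  Every model-mean vertex
    is matched to its exact closest point on the partial surface; matches
    within ``accept_dist`` mm become observations, unmatched vertices are
    the candidate missing region.

    ``from_vertices`` substitutes updated positions of the model vertices
    (e.g. a current posterior mean) as the match sources while keeping
    model-vertex indexing — used when fitting iteratively.
    """
    mean_vertices = (
        pdm.mean.reshape(-1, 3) if from_vertices is None else from_vertices
    )
    dists, closest, tri = SurfaceQuery(partial).query(mean_vertices)
    accept = dists <= accept_dist
    # matches landing on triangles at the specimen's open boundary (the
    # damage rim) are not genuine surface correspondences — a model vertex
    # beyond the rim snaps to the rim edge and would drag the fit; drop
    # them (standard practice when registering partial scans)
    directed = partial.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    rim_vertices = np.unique(uniq[counts == 1])
    if len(rim_vertices):
        on_rim = np.isin(partial.faces[tri], rim_vertices).any(axis=1)
        accept &= ~on_rim
    # normal-consistency gate: a model vertex sitting beyond the damage
    # boundary can pass close to the intact surface while facing a
    # different way (a neck stub grazing the outer shaft); such grazing
    # matches would "observe" missing anatomy at the wrong surface
    model_mesh = TriangleMesh(mean_vertices, pdm.faces)
    vn = model_mesh.vertex_normals()
    ptri = partial.vertices[partial.faces[tri]]
    tn = np.cross(ptri[:, 1] - ptri[:, 0], ptri[:, 2] - ptri[:, 0])
    norms = np.linalg.norm(tn, axis=1)
    tn = tn / np.where(norms > 0, norms, 1.0)[:, None]
    accept &= np.einsum("ij,ij->i", vn, tn) > 0.5
    if accept.sum() < 3:
        raise ValueError(
            "partial mesh does not overlap model: "
            f"{int(accept.sum())} vertices within {accept_dist} mm"
        )
    return PartialObservations(
        indices=np.flatnonzero(accept),
        points=closest[accept],
        sigma2=float(sigma2),
        normals=tn[accept],
    )


def posterior(
    pdm: PointDistributionModel,
    obs: PartialObservations,
    point_to_plane: bool = False,
) -> PosteriorModel:
    """Gaussian-process posterior of the shape model given observations.

    With ``point_to_plane`` (requires observation normals) each match
    constrains only the displacement component along the observed-surface
    normal.  Closest-point matching measures exactly that component —
    the tangential part of a match is an artefact of the perpendicular
    foot — so point-to-plane avoids spuriously penalising tangential
    (sliding/stretching) shape modes during iterative fitting.
    """
    r = pdm.rank
    sqrt_lam = np.sqrt(pdm.variances)
    rows = np.stack(
        [3 * obs.indices, 3 * obs.indices + 1, 3 * obs.indices + 2], axis=1
    ).ravel()
    Q = pdm.basis[rows] * sqrt_lam  # (3m, r)
    y = (obs.points - pdm.mean.reshape(-1, 3)[obs.indices]).ravel()
    if point_to_plane:
        if obs.normals is None:
            raise ValueError("point_to_plane requires observation normals")
        m = len(obs)
        Q3 = Q.reshape(m, 3, r)
        Q = np.einsum("mi,mir->mr", obs.normals, Q3)  # (m, r)
        y = np.einsum("mi,mi->m", obs.normals, y.reshape(m, 3))
    A = np.eye(r) + (Q.T @ Q) / obs.sigma2
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        log.warning("posterior system near-singular; adding 1e-10 jitter")
        cho = np.linalg.cholesky(A + 1e-10 * np.eye(r))
    ident = np.eye(r)
    A_inv = np.linalg.solve(cho.T, np.linalg.solve(cho, ident))
    m_alpha = A_inv @ (Q.T @ y / obs.sigma2)
    mu_post = pdm.mean + pdm.basis @ (sqrt_lam * m_alpha)
    # shape-space posterior covariance factor: Phi (L^1/2 Sigma L^1/2) Phi^T
    S = (sqrt_lam[:, None] * A_inv) * sqrt_lam[None, :]
    S = 0.5 * (S + S.T)
    gamma, V = np.linalg.eigh(S)
    order = np.argsort(gamma)[::-1]
    gamma, V = np.maximum(gamma[order], 0.0), V[:, order]
    keep = gamma > 1e-14 * (gamma[0] if gamma[0] > 0 else 1.0)
    post_basis = pdm.basis @ V[:, keep]
    # canonical mode orientation: +k SD inflates the shape (positive
    # projection onto the outward field about the centroid), so the SD
    # axis of the variant family reads largest at +3 when the leading
    # mode is a size mode; falls back to largest-entry-positive
    centred = (
        mu_post.reshape(-1, 3) - mu_post.reshape(-1, 3).mean(axis=0)
    ).ravel()
    proj = post_basis.T @ centred
    signs = np.where(
        np.abs(proj) > 1e-6 * np.linalg.norm(centred),
        np.sign(proj),
        np.sign(
            post_basis[
                np.argmax(np.abs(post_basis), axis=0),
                np.arange(post_basis.shape[1]),
            ]
        ),
    )
    signs[signs == 0] = 1.0
    post_basis = post_basis * signs
    post_model = PointDistributionModel(
        faces=pdm.faces.copy(),
        mean=mu_post,
        basis=post_basis,
        variances=gamma[keep],
        n_training=pdm.n_training,
        frame=pdm.frame,
        metadata={**pdm.metadata, "posterior": {"sigma2": obs.sigma2,
                                                "n_obs": len(obs)}},
    )
    intact = np.zeros(pdm.n_vertices, dtype=bool)
    intact[obs.indices] = True
    return PosteriorModel(post_model, intact, obs)


def reconstruct_variants(
    post: PosteriorModel,
    levels=DEFAULT_VARIANT_LEVELS,
    joint: bool = False,
) -> list[TriangleMesh]:
    """The +/-k SD family of statistical reconstructions.

    Level 0 is the posterior mean; level +/-k moves k posterior standard
    deviations along the first posterior mode (or along every mode
    jointly when ``joint``).  The default seven levels are -3..+3.
    """
    model = post.model
    out = []
    if model.rank == 0:
        log.warning("posterior basis is empty; emitting level 0 only")
        mesh = model.mean_mesh()
        mesh.name = "statrecon-mean"
        return [mesh]
    for k in levels:
        alpha = np.zeros(model.rank)
        if joint:
            alpha[:] = float(k)
        else:
            alpha[0] = float(k)
        name = (
            "statrecon-mean"
            if k == 0
            else f"statrecon-{'+' if k > 0 else ''}{k}sd"
        )
        out.append(model.instance(alpha, name=name))
    return out


def _blend_weights(
    mesh: TriangleMesh, intact: np.ndarray, band: float
) -> np.ndarray:
    """Per-vertex snap weight: 1 deep in the intact region, 0 elsewhere,
    ramping linearly across ``band`` mm (graph geodesic) of the label
    boundary on the intact side."""
    w = np.zeros(mesh.n_vertices)
    if band <= 0:
        w[intact] = 1.0
        return w
    edges = mesh.edges_unique()
    boundary = intact[edges[:, 0]] != intact[edges[:, 1]]
    seeds = np.unique(edges[boundary])
    if len(seeds) == 0:
        w[intact] = 1.0
        return w
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    n = mesh.n_vertices
    graph = csr_matrix(
        (
            np.concatenate([lengths, lengths]),
            (
                np.concatenate([edges[:, 0], edges[:, 1]]),
                np.concatenate([edges[:, 1], edges[:, 0]]),
            ),
        ),
        shape=(n, n),
    )
    dist = dijkstra(graph, indices=seeds, min_only=True, limit=band * 1.5)
    dist = np.where(np.isfinite(dist), dist, band * 1.5)
    w[intact] = np.clip(dist[intact] / band, 0.0, 1.0)
    return w


def stitch_reconstruction(
    post: PosteriorModel,
    partial: TriangleMesh,
    band: float = 5.0,
) -> TriangleMesh:
    """Combine measured intact geometry with the statistical completion.

    Keeps the posterior topology: vertices labelled intact are snapped to
    their closest points on the partial surface, reconstructed vertices
    take the posterior-mean positions, and a band of the given width
    (mm, geodesic) ramps linearly between the two across the label
    boundary.  ``band=0`` gives the raw piecewise result.
    """
    mean_vertices = post.model.mean.reshape(-1, 3).copy()
    intact = post.intact
    if intact.any():
        _, snapped, _ = SurfaceQuery(partial).query(mean_vertices[intact])
    else:
        snapped = np.empty((0, 3))
    mesh = post.model.mean_mesh()
    w = _blend_weights(mesh, intact, band)
    out = mean_vertices
    out[intact] = (
        w[intact, None] * snapped + (1.0 - w[intact, None]) * out[intact]
    )
    return TriangleMesh(out, post.model.faces.copy(), name="stitched")
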