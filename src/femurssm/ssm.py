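"""The statistical shape model: a PCA point-distribution model (PDM).

Corresponded meshes (one topology, vertex-wise comparable) are stacked as
3N-vectors; the model is the vertex-wise mean plus an orthonormal basis of
variation modes with per-mode variances, obtained from the sample
covariance (divisor n-1) via the n x n Gram matrix (n << 3N).  Shape
coefficients are expressed in standard-deviation units per mode, so an
instance is

    x(alpha) = mu + Phi diag(sqrt(lambda)) alpha

and "+2 SD of mode 1" is literally alpha = (2, 0, ..., 0).

``augment`` adds a Gaussian-kernel covariance to the PCA covariance
(C = C_pca + k_gauss), which spreads plausible variation beyond the span
of the training sample and makes the model robust to residual
correspondence noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .correspondence import (
    LowRankDeformationModel,
    _orient_columns,
    gaussian_kernel_basis,
)
from .mesh import TriangleMesh

__all__ = [
    "PointDistributionModel",
    "build_pdm",
    "augment",
    "save_model",
    "load_model",
    "save_deformation_model",
    "load_deformation_model",
]

log = logging.getLogger(__name__)


@dataclass
class PointDistributionModel:
    """Mean shape + orthonormal variation modes over one topology."""

    faces: np.ndarray  # (M, 3) reference topology
    mean: np.ndarray  # (3N,) mm, interleaved x0 y0 z0 x1 ...
    basis: np.ndarray  # (3N, r), orthonormal columns
    variances: np.ndarray  # (r,), mm^2, descending, >= 0
    n_training: int = 0
    frame: str = "canonical"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.mean = np.ascontiguousarray(self.mean, dtype=np.float64)
        self.basis = np.ascontiguousarray(self.basis, dtype=np.float64)
        self.variances = np.ascontiguousarray(
            self.variances, dtype=np.float64
        )
        r = self.rank
        if self.basis.shape[0] != self.mean.shape[0]:
            raise ValueError("basis rows != mean length")
        if self.mean.shape[0] % 3:
            raise ValueError("mean length must be a multiple of 3")
        if len(self.variances) != r:
            raise ValueError("variances length != rank")
        if (np.diff(self.variances) > 1e-9).any():
            raise ValueError("variances must be sorted descending")
        if (self.variances < 0).any():
            raise ValueError("variances must be non-negative")
        if r:
            gram = self.basis.T @ self.basis
            if not np.allclose(gram, np.eye(r), atol=1e-8):
                raise ValueError("basis columns not orthonormal (1e-8)")

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.mean.shape[0] // 3

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(
            self.mean.reshape(-1, 3).copy(), self.faces.copy(), name="mean"
        )

    def instance(
        self, alpha: np.ndarray, name: str | None = None
    ) -> TriangleMesh:
        """Shape at coefficients ``alpha`` (SD units per mode)."""
        alpha = np.asarray(alpha, dtype=np.float64)
        if alpha.shape != (self.rank,):
            raise ValueError(
                f"alpha must have length {self.rank}, got {alpha.shape}"
            )
        x = self.mean + self.basis @ (np.sqrt(self.variances) * alpha)
        return TriangleMesh(x.reshape(-1, 3), self.faces.copy(), name=name)

    def sample(self, seed: int) -> TriangleMesh:
        """Random shape with standard-normal coefficients."""
        rng = np.random.default_rng(seed)
        return self.instance(
            rng.standard_normal(self.rank), name=f"sample-{seed}"
        )

    def project(self, mesh: TriangleMesh) -> np.ndarray:
        """Coefficients (SD units) of the best basis approximation."""
        d = mesh.vertices.ravel() - self.mean
        raw = self.basis.T @ d
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(
                self.variances > 0, raw / np.sqrt(self.variances), 0.0
            )
        return alpha

    def variance_table(self) -> str:
        """Per-mode variance table (mode, lambda, cumulative %)."""
        total = self.variances.sum() or 1.0
        lines = ["mode  variance_mm2  cumulative_pct"]
        cum = 0.0
        for i, lam in enumerate(self.variances, start=1):
            cum += lam
            lines.append(f"{i:4d}  {lam:12.4f}  {100 * cum / total:13.2f}")
        return "\n".join(lines)


def build_pdm(meshes: list[TriangleMesh]) -> PointDistributionModel:
    """PCA point-distribution model from corresponded meshes.

    Uses the n x n Gram matrix of centred shape vectors; modes with
    variance < 1e-10 of the leading mode are dropped, so the rank is at
    most n - 1.  Eigenvector signs are fixed deterministically (largest
    entry positive), making the result independent of input ordering up
    to degenerate eigenvalues.
    """
    if len(meshes) < 2:
        raise ValueError("need at least 2 meshes")
    ref = meshes[0]
    for i, m in enumerate(meshes[1:], start=1):
        if m.n_vertices != ref.n_vertices or not np.array_equal(
            m.faces, ref.faces
        ):
            raise ValueError(
                f"mesh {i} ({m.name!r}) does not share the reference "
                "topology"
            )
    X = np.stack([m.vertices.ravel() for m in meshes])  # (n, 3N)
    n = len(X)
    mu = X.mean(axis=0)
    Xc = X - mu
    gram = (Xc @ Xc.T) / (n - 1)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 0.0)
    keep = evals > 1e-10 * (evals[0] if evals[0] > 0 else 1.0)
    keep[min(n - 1, len(keep)) :] = False
    evals, evecs = evals[keep], evecs[:, keep]
    # basis = Xc^T V / sqrt((n-1) lambda)
    basis = Xc.T @ (evecs / np.sqrt((n - 1) * evals))
    basis = _orient_columns(basis)
    return PointDistributionModel(
        faces=ref.faces.copy(),
        mean=mu,
        basis=basis,
        variances=evals,
        n_training=n,
    )


def augment(
    pdm: PointDistributionModel,
    s: float,
    lengthscale: float,
    rank_out: int | None = None,
    n_inducing: int = 500,
    seed: int = 0,
) -> PointDistributionModel:
    """Add Gaussian-kernel covariance to the model covariance.

    The output covariance approximates C_pca + k_gauss, re-expressed as an
    orthonormal basis with descending variances by an SVD of the combined
    low-rank factor.  ``rank_out`` defaults to rank + 50 and must not be
    smaller than the input rank.
    """
    if rank_out is None:
        rank_out = pdm.rank + 50
    if rank_out < pdm.rank:
        raise ValueError(
            f"rank_out ({rank_out}) must be >= input rank ({pdm.rank})"
        )
    if s == 0.0:
        return PointDistributionModel(
            faces=pdm.faces.copy(),
            mean=pdm.mean.copy(),
            basis=pdm.basis.copy(),
            variances=pdm.variances.copy(),
            n_training=pdm.n_training,
            frame=pdm.frame,
            metadata={**pdm.metadata, "augmented": {"s": 0.0}},
        )
    k_rank = min(rank_out - pdm.rank + 50, 3 * pdm.n_vertices)
    k_basis, k_var = gaussian_kernel_basis(
        pdm.mean.reshape(-1, 3),
        s=s,
        lengthscale=lengthscale,
        rank=k_rank,
        n_inducing=min(n_inducing, pdm.n_vertices),
        seed=seed,
    )
    # combined low-rank factor F F^T = C_pca + k_gauss
    F = np.hstack(
        [pdm.basis * np.sqrt(pdm.variances), k_basis * np.sqrt(k_var)]
    )
    U, sv, _ = np.linalg.svd(F, full_matrices=False)
    keep = min(rank_out, (sv > 1e-12 * sv[0]).sum())
    U = _orient_columns(U[:, :keep])
    return PointDistributionModel(
        faces=pdm.faces.copy(),
        mean=pdm.mean.copy(),
        basis=U,
        variances=sv[:keep] ** 2,
        n_training=pdm.n_training,
        frame=pdm.frame,
        metadata={
            **pdm.metadata,
            "augmented": {"s": float(s), "lengthscale": float(lengthscale)},
        },
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def save_model(pdm: PointDistributionModel, path) -> None:
    with h5py.File(path, "w") as f:
        ref = f.create_group("reference")
        ref.create_dataset("vertices", data=pdm.mean.reshape(-1, 3))
        ref.create_dataset("faces", data=pdm.faces)
        f.create_dataset("mean", data=pdm.mean)
        f.create_dataset("basis", data=pdm.basis)
        f.create_dataset("variances", data=pdm.variances)
        f.create_dataset("n_training", data=pdm.n_training)
        f.attrs["frame"] = pdm.frame
        f.attrs["metadata"] = json.dumps(pdm.metadata)
        f.attrs["kind"] = "point_distribution_model"


def load_model(path) -> PointDistributionModel:
    with h5py.File(path, "r") as f:
        return PointDistributionModel(
            faces=f["reference/faces"][()],
            mean=f["mean"][()],
            basis=f["basis"][()],
            variances=f["variances"][()],
            n_training=int(f["n_training"][()]),
            frame=str(f.attrs.get("frame", "canonical")),
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


def save_deformation_model(model: LowRankDeformationModel, path) -> None:
    with h5py.File(path, "w") as f:
        ref = f.create_group("reference")
        ref.create_dataset("vertices", data=model.reference.vertices)
        ref.create_dataset("faces", data=model.reference.faces)
        f.create_dataset("basis", data=model.basis)
        f.create_dataset("variances", data=model.variances)
        kp = f.create_group("kernel_params")
        for k, v in model.kernel_params.items():
            kp.attrs[k] = v
        f.attrs["kind"] = "deformation_model"


def load_deformation_model(path) -> LowRankDeformationModel:
    with h5py.File(path, "r") as f:
        return LowRankDeformationModel(
            reference=TriangleMesh(
                f["reference/vertices"][()], f["reference/faces"][()]
            ),
            basis=f["basis"][()],
            variances=f["variances"][()],
            kernel_params=dict(f["kernel_params"].attrs),
        )
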