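"""End-to-end orchestration: population -> SSM -> reconstruction -> report.

The library modules stay independent; this module wires them into the
standard workflow and owns the run configuration:

1. clean + decimate every healthy mesh to a standard face budget,
2. rigidly align the population (pseudo-landmark ICP),
3. non-rigidly register a reference onto every specimen (correspondence),
4. PCA -> point-distribution model, then Gaussian-kernel augmentation,
5. fit the model to a damaged specimen and emit the 7 SD variants,
6. measure the five femur morphometrics per variant.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation as _Rotation

from . import reconstruction as recon
from .alignment import icp_rigid
from .correspondence import build_deformation_model, nonrigid_register
from .decimate import decimate
from .mesh import RigidTransform, TriangleMesh, apply_rigid, keep_largest_component
from .morphometrics import MorphometricsReport, derive_axes, measure_all
from .ssm import PointDistributionModel, augment, build_pdm

__all__ = ["PipelineConfig", "build_ssm_pipeline", "reconstruct_pipeline",
           "measure_variants"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the workflow, with protocol defaults."""

    # mesh standardisation
    target_faces: int = 10000
    # rigid alignment (pseudo-landmark ICP)
    n_landmarks: int = 50
    icp_max_iter: int = 150
    # non-rigid registration
    n_points: int = 1000
    reg_max_iter: int = 100
    kernel_s: float = 10.0
    kernel_lengthscale: float | None = None  # None: 0.25 * bbox diagonal
    kernel_rank: int = 150
    n_inducing: int = 500
    sigma2_start: float = 1.0
    sigma2_floor: float = 0.1
    anneal: float = 0.95
    resample_points: bool = False
    # augmentation
    augment_s: float = 2.0
    augment_lengthscale: float | None = None
    augment_extra_rank: int = 50
    # reconstruction
    accept_dist: float = 5.0
    obs_sigma2: float = 1.0
    fit_sigma2_floor: float = 0.1
    fit_anneal: float = 0.9
    fit_iterations: int = 40
    variant_levels: tuple = recon.DEFAULT_VARIANT_LEVELS
    joint_variants: bool = False
    stitch_band: float = 5.0
    # synthetic data
    resolution: float = 2.0
    population_n: int = 35
    # misc
    seed: int = 0
    reference_index: int = 0

    def validate(self) -> None:
        checks = [
            (self.target_faces >= 4, "target_faces >= 4"),
            (1 <= self.n_landmarks, "n_landmarks >= 1"),
            (1 <= self.icp_max_iter, "icp_max_iter >= 1"),
            (3 <= self.n_points, "n_points >= 3"),
            (1 <= self.reg_max_iter, "reg_max_iter >= 1"),
            (self.kernel_s > 0, "kernel_s > 0"),
            (self.sigma2_start > 0, "sigma2_start > 0"),
            (0 < self.anneal <= 1, "anneal in (0, 1]"),
            (self.accept_dist > 0, "accept_dist > 0"),
            (self.obs_sigma2 > 0, "obs_sigma2 > 0"),
            (self.resolution > 0, "resolution > 0"),
            (self.augment_s >= 0, "augment_s >= 0"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"invalid config: requires {what}")

    # -- serialisation -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["variant_levels"] = list(self.variant_levels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "variant_levels" in data:
            data["variant_levels"] = tuple(data["variant_levels"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        data = asdict(self)
        data["variant_levels"] = list(self.variant_levels)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SSMBuildResult:
    model: PointDistributionModel  # augmented model used for fitting
    pdm: PointDistributionModel  # raw PCA model
    corresponded: list  # CorrespondedMesh per specimen
    transforms: list  # rigid alignment per specimen
    registration_residuals: list  # final residual per specimen, mm
    reference_index: int


def standardize_mesh(mesh: TriangleMesh, config: PipelineConfig) -> TriangleMesh:
    """Largest component + quadric decimation to the standard face budget."""
    m = keep_largest_component(mesh)
    return decimate(m, config.target_faces)


def register_population(
    meshes: list[TriangleMesh],
    config: PipelineConfig | None = None,
    standardized: bool = False,
) -> tuple[list, list, object, list]:
    """Align + bring a population into dense correspondence.

    Each specimen is rigidly ICP-aligned to the reference specimen, then
    the reference is non-rigidly registered onto it.  Registrations are
    independent across specimens (each uses only the reference and that
    specimen), so subsets can be recombined, e.g. for hold-out studies.

    Returns (corresponded meshes, rigid transforms, deformation model,
    final registration residuals in mm).
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if len(meshes) < 2:
        raise ValueError("population needs at least 2 meshes")
    if not standardized:
        meshes = [standardize_mesh(m, cfg) for m in meshes]

    ref_idx = cfg.reference_index
    reference = meshes[ref_idx]
    dmodel = build_deformation_model(
        reference,
        s=cfg.kernel_s,
        lengthscale=cfg.kernel_lengthscale,
        rank=cfg.kernel_rank,
        n_inducing=cfg.n_inducing,
        seed=cfg.seed,
    )
    corresponded, transforms, residuals = [], [], []
    for i, m in enumerate(meshes):
        if i == ref_idx:
            aligned = m
            transforms.append(RigidTransform.identity())
        else:
            res = icp_rigid(
                m,
                reference,
                n_landmarks=cfg.n_landmarks,
                max_iter=cfg.icp_max_iter,
                seed=cfg.seed,
            )
            log.info(
                "aligned specimen %d: rms %.3f mm (%d iters)",
                i,
                res.rms_residual,
                res.iterations,
            )
            aligned = apply_rigid(m, res.transform)
            transforms.append(res.transform)
        reg = nonrigid_register(
            dmodel,
            aligned,
            n_points=cfg.n_points,
            max_iter=cfg.reg_max_iter,
            sigma2_start=cfg.sigma2_start,
            sigma2_floor=cfg.sigma2_floor,
            anneal=cfg.anneal,
            seed=cfg.seed,
            resample=cfg.resample_points,
            full_output=True,
        )
        log.info(
            "registered specimen %d: residual %.3f mm (%d iters)",
            i,
            reg.residuals[-1],
            reg.iterations,
        )
        corresponded.append(reg.mesh)
        residuals.append(reg.residuals[-1])
    return corresponded, transforms, dmodel, residuals


def finalize_model(
    corresponded: list,
    config: PipelineConfig | None = None,
    reference: TriangleMesh | None = None,
) -> tuple[PointDistributionModel, PointDistributionModel]:
    """Procrustes-clean corresponded meshes -> (raw PDM, augmented model).

    Exact Procrustes on the corresponded meshes removes residual pose
    variance that would otherwise surface as spurious PCA modes.
    """
    cfg = config or PipelineConfig()
    from .alignment import procrustes_align
    from .correspondence import CorrespondedMesh

    ref_mesh = reference or corresponded[0]
    cleaned = [
        CorrespondedMesh(m.vertices, corresponded[0], name=m.name)
        for m in procrustes_align(corresponded)
    ]
    pdm = build_pdm(cleaned)
    if cfg.augment_s > 0:
        model = augment(
            pdm,
            s=cfg.augment_s,
            lengthscale=cfg.augment_lengthscale
            or 0.25 * ref_mesh.bbox_diagonal(),
            rank_out=pdm.rank + cfg.augment_extra_rank,
            n_inducing=cfg.n_inducing,
            seed=cfg.seed,
        )
    else:
        model = pdm
    return pdm, model


def build_ssm_pipeline(
    meshes: list[TriangleMesh],
    config: PipelineConfig | None = None,
    standardized: bool = False,
) -> SSMBuildResult:
    """Healthy population -> augmented statistical shape model."""
    cfg = config or PipelineConfig()
    cfg.validate()
    corresponded, transforms, dmodel, residuals = register_population(
        meshes, cfg, standardized=standardized
    )
    pdm, model = finalize_model(
        corresponded, cfg, reference=dmodel.reference
    )
    return SSMBuildResult(
        model=model,
        pdm=pdm,
        corresponded=corresponded,
        transforms=transforms,
        registration_residuals=residuals,
        reference_index=cfg.reference_index,
    )


@dataclass
class ReconstructionResult:
    variants: list  # 7 TriangleMesh, model frame
    stitched: TriangleMesh
    posterior: recon.PosteriorModel
    transform: RigidTransform  # partial -> model frame
    metadata: dict

    def variants_in_scan_frame(self) -> list:
        inv = self.transform.inverse()
        return [apply_rigid(v, inv) for v in self.variants]


def reconstruct_pipeline(
    model: PointDistributionModel,
    partial: TriangleMesh,
    config: PipelineConfig | None = None,
    prealigned: bool = False,
) -> ReconstructionResult:
    """Damaged specimen -> posterior model, 7 SD variants, stitched mesh."""
    cfg = config or PipelineConfig()
    cfg.validate()
    mean_mesh = model.mean_mesh()
    if prealigned:
        transform = RigidTransform.identity()
        aligned = partial
    else:
        res = icp_rigid(
            partial,
            mean_mesh,
            n_landmarks=cfg.n_landmarks,
            max_iter=cfg.icp_max_iter,
            seed=cfg.seed,
        )
        transform = res.transform
        aligned = apply_rigid(partial, transform)
    # iterative fitting: plain ICP of a partial mesh onto the full mean
    # is biased by the non-overlapping region, and pose is degenerate
    # with the leading (size) mode along the shaft, so pose and shape
    # increments are solved JOINTLY from point-to-plane matches each
    # iteration (pose columns free, shape coefficients under the model
    # prior), re-matching against the current estimate
    sqrt_lam = np.sqrt(model.variances)
    alpha = np.zeros(model.rank)
    sigma2 = cfg.obs_sigma2
    obs = None
    center = model.mean.reshape(-1, 3).mean(axis=0)
    for _ in range(max(1, cfg.fit_iterations)):
        current = (
            model.mean + model.basis @ (sqrt_lam * alpha)
        ).reshape(-1, 3)
        obs = recon.establish_partial_correspondence(
            model,
            aligned,
            accept_dist=cfg.accept_dist,
            sigma2=sigma2,
            seed=cfg.seed,
            from_vertices=current,
        )
        n = obs.normals
        idx = obs.indices
        x = current[idx]
        resid = np.einsum("mi,mi->m", n, obs.points - x)
        rows = np.stack([3 * idx, 3 * idx + 1, 3 * idx + 2], axis=1).ravel()
        Q3 = (model.basis[rows] * sqrt_lam).reshape(len(idx), 3, -1)
        Qn = np.einsum("mi,mir->mr", n, Q3)
        if prealigned:
            A = Qn
            n_pose = 0
        else:
            # pose columns: translation n, rotation n . (e_j x (x - c))
            arm = x - center
            rot_cols = np.stack(
                [
                    np.einsum("mi,mi->m", n, np.cross(e, arm))
                    for e in np.eye(3)
                ],
                axis=1,
            )
            A = np.hstack([n, rot_cols, Qn])
            n_pose = 6
        r = model.rank
        reg = np.zeros((n_pose + r, n_pose + r))
        reg[n_pose:, n_pose:] = np.eye(r)
        rhs = A.T @ resid / sigma2
        rhs[n_pose:] -= alpha
        sol = np.linalg.solve(A.T @ A / sigma2 + reg, rhs)
        alpha = alpha + sol[n_pose:]
        if not prealigned:
            t_inc, w_inc = sol[:3], sol[3:6]
            # small-angle pose increment moves the MODEL towards the
            # data; apply its inverse to the partial instead
            R_inc = _Rotation.from_rotvec(w_inc).as_matrix()
            pose = RigidTransform(R_inc, t_inc + center - R_inc @ center)
            inv = pose.inverse()
            aligned = apply_rigid(aligned, inv)
            transform = inv.compose(transform)
        step = float(np.abs(sol).max())
        sigma2 = max(sigma2 * cfg.fit_anneal, cfg.fit_sigma2_floor)
        if step < 1e-4:
            break
    # final posterior (covariance and labels) in the converged frame
    final_vertices = (
        model.mean + model.basis @ (sqrt_lam * alpha)
    ).reshape(-1, 3)
    obs = recon.establish_partial_correspondence(
        model,
        aligned,
        accept_dist=cfg.accept_dist,
        sigma2=sigma2,
        seed=cfg.seed,
        from_vertices=final_vertices,
    )
    post = recon.posterior(model, obs, point_to_plane=True)
    variants = recon.reconstruct_variants(
        post, levels=cfg.variant_levels, joint=cfg.joint_variants
    )
    stitched = recon.stitch_reconstruction(post, aligned, band=cfg.stitch_band)
    metadata = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_observed": int(len(obs)),
        "n_vertices": int(model.n_vertices),
        "observed_fraction": float(len(obs) / model.n_vertices),
        "variant_levels": list(cfg.variant_levels),
        "variant_axis": "joint" if cfg.joint_variants else "first_mode",
        "accept_dist_mm": cfg.accept_dist,
        "obs_sigma2_mm2": cfg.obs_sigma2,
        "posterior_total_variance_mm2": float(post.model.variances.sum()),
        "transform_to_model_frame": transform.to_matrix().tolist(),
    }
    return ReconstructionResult(variants, stitched, post, transform, metadata)


def measure_variants(
    variants: list,
    reference_mean: TriangleMesh,
    extra: list | None = None,
    hints: dict | None = None,
) -> list[MorphometricsReport]:
    """Morphometrics rows for the variant family (plus optional extras,
    e.g. the prosthesis-bearing mesh), all against the reconstruction
    mean.  ``hints`` are landmark overrides applied to every mesh."""
    ref_axes = derive_axes(reference_mean, hints=hints)
    rows = []
    for mesh in (extra or []) + list(variants):
        rows.append(
            measure_all(
                mesh, reference_mean, reference_axes=ref_axes, hints=hints
            )
        )
    return rows
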