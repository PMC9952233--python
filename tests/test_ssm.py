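import numpy as np
import pytest

from femurssm.mesh import TriangleMesh
from femurssm.ssm import (
    augment,
    build_pdm,
    load_model,
    save_model,
)

from conftest import icosphere


def deformed_spheres(n, seed=0, direction_seed=1, scale=2.0):
    """Population = sphere + a_i * d for one fixed random direction d."""
    base = icosphere(1, radius=10.0)
    rng_d = np.random.default_rng(direction_seed)
    d = rng_d.normal(size=base.vertices.shape)
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(scale=scale, size=n)
    meshes = [
        TriangleMesh(base.vertices + a * d, base.faces) for a in coeffs
    ]
    return meshes, d, coeffs


class TestBuildPDM:
    def test_two_meshes_single_mode_midpoint_mean(self):
        meshes, _, _ = deformed_spheres(2)
        pdm = build_pdm(meshes)
        assert pdm.rank == 1
        mid = 0.5 * (meshes[0].vertices + meshes[1].vertices)
        assert np.allclose(pdm.mean.reshape(-1, 3), mid, atol=1e-12)

    def test_single_direction_population_one_dominant_mode(self):
        meshes, d, coeffs = deformed_spheres(12, scale=2.0)
        pdm = build_pdm(meshes)
        lam_expected = np.var(coeffs, ddof=1) * (d.ravel() ** 2).sum()
        assert np.isclose(pdm.variances[0], lam_expected, rtol=1e-9)
        if pdm.rank > 1:
            assert pdm.variances[1] / pdm.variances[0] < 1e-8

    def test_training_shapes_reconstructed_exactly(self):
        meshes, _, _ = deformed_spheres(5)
        pdm = build_pdm(meshes)
        for m in meshes:
            alpha = pdm.project(m)
            back = pdm.instance(alpha)
            assert np.abs(back.vertices - m.vertices).max() < 1e-6

    def test_order_invariance(self):
        meshes, _, _ = deformed_spheres(8)
        a = build_pdm(meshes)
        b = build_pdm(meshes[::-1])
        assert np.allclose(a.mean, b.mean, atol=1e-12)
        assert np.allclose(a.variances, b.variances, atol=1e-9)
        # spanned subspaces coincide (principal angles ~ 0)
        sv = np.linalg.svd(a.basis.T @ b.basis, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(sv, -1, 1)))
        assert angles.max() < 1e-6

    def test_mismatched_topology_rejected(self):
        meshes, _, _ = deformed_spheres(3)
        odd = icosphere(2)
        odd.name = "intruder"
        with pytest.raises(ValueError, match="intruder"):
            build_pdm(meshes + [odd])


class TestInstanceAndSample:
    def test_alpha_zero_is_mean(self, small_pdm):
        inst = small_pdm.instance(np.zeros(small_pdm.rank))
        assert np.array_equal(
            inst.vertices.ravel(), small_pdm.mean
        )

    def test_opposite_coefficients_reflect_about_mean(self, small_pdm):
        rng = np.random.default_rng(0)
        alpha = rng.normal(size=small_pdm.rank)
        plus = small_pdm.instance(alpha).vertices
        minus = small_pdm.instance(-alpha).vertices
        avg = 0.5 * (plus + minus)
        assert np.abs(avg - small_pdm.mean.reshape(-1, 3)).max() < 1e-9

    def test_wrong_coefficient_length_rejected(self, small_pdm):
        with pytest.raises(ValueError):
            small_pdm.instance(np.zeros(small_pdm.rank + 2))

    def test_sample_deterministic(self, small_pdm):
        a = small_pdm.sample(123)
        b = small_pdm.sample(123)
        assert np.array_equal(a.vertices, b.vertices)

    def test_sample_mean_converges_to_model_mean(self, small_pdm):
        # variances <= 25 mm^2 -> per-vertex sd <= ~5 mm spread over modes
        acc = np.zeros_like(small_pdm.mean)
        n = 2000
        for s in range(n):
            acc += small_pdm.sample(s).vertices.ravel()
        err = np.abs(acc / n - small_pdm.mean).max()
        assert err < 0.15

    def test_recovered_coefficient_variance_near_unit(self, small_pdm):
        alphas = np.stack(
            [small_pdm.project(small_pdm.sample(s)) for s in range(2000)]
        )
        var = alphas.var(axis=0)
        assert np.abs(var - 1.0).max() < 0.1


class TestAugment:
    def test_zero_kernel_is_identity(self, small_pdm):
        out = augment(small_pdm, s=0.0, lengthscale=10.0)
        assert np.allclose(out.variances, small_pdm.variances)
        assert np.allclose(out.basis, small_pdm.basis)

    def test_total_variance_never_decreases(self, small_pdm):
        out = augment(small_pdm, s=2.0, lengthscale=10.0, rank_out=40)
        assert out.variances.sum() >= small_pdm.variances.sum() - 1e-9

    def test_rank_out_below_input_rejected(self, small_pdm):
        with pytest.raises(ValueError):
            augment(small_pdm, s=1.0, lengthscale=5.0, rank_out=1)

    def test_matches_dense_covariance_sum(self):
        """Densified augmented covariance ~= C_pca + dense kernel."""
        meshes, _, _ = deformed_spheres(6)  # 42-vertex spheres
        pdm = build_pdm(meshes)
        n = pdm.n_vertices
        s, ell = 2.0, 8.0
        out = augment(
            pdm, s=s, lengthscale=ell, rank_out=3 * n, n_inducing=n
        )
        C_out = (out.basis * out.variances) @ out.basis.T
        C_pca = (pdm.basis * pdm.variances) @ pdm.basis.T
        pts = pdm.mean.reshape(-1, 3)
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        K = np.kron(s**2 * np.exp(-0.5 * d2 / ell**2), np.eye(3))
        target = C_pca + K
        rel = np.linalg.norm(C_out - target) / np.linalg.norm(target)
        assert rel < 0.05


class TestContainer:
    def test_hdf5_roundtrip(self, small_pdm, tmp_path):
        path = tmp_path / "model.h5"
        small_pdm.metadata["note"] = "roundtrip"
        save_model(small_pdm, path)
        back = load_model(path)
        assert np.allclose(back.mean, small_pdm.mean)
        assert np.allclose(back.basis, small_pdm.basis)
        assert np.allclose(back.variances, small_pdm.variances)
        assert back.metadata["note"] == "roundtrip"
        assert back.frame == small_pdm.frame

    def test_variance_table_format(self, small_pdm):
        table = small_pdm.variance_table()
        lines = table.splitlines()
        assert len(lines) == 1 + small_pdm.rank
        assert lines[-1].split()[-1] == "100.00"
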