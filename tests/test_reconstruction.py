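import numpy as np
import pytest

from femurssm.reconstruction import (
    PartialObservations,
    establish_partial_correspondence,
    posterior,
    reconstruct_variants,
    stitch_reconstruction,
)


class TestPartialObservations:
    def test_invariants(self):
        pts = np.zeros((3, 3))
        with pytest.raises(ValueError):
            PartialObservations(np.array([0, 1]), pts, 1.0)
        with pytest.raises(ValueError):
            PartialObservations(np.array([0, 1, 1]), pts, 1.0)
        with pytest.raises(ValueError):
            PartialObservations(np.array([0, 1, 2]), pts, 0.0)


class TestPosterior:
    def test_uninformative_noise_keeps_prior(self, small_pdm):
        """sigma^2 -> infinity: the posterior reverts to the prior."""
        idx = np.array([0, 5, 10])
        pts = small_pdm.mean.reshape(-1, 3)[idx] + 3.0
        obs = PartialObservations(idx, pts, sigma2=1e12)
        post = posterior(small_pdm, obs)
        assert np.allclose(post.model.mean, small_pdm.mean, atol=1e-4)
        assert np.allclose(
            np.sort(post.model.variances)[::-1],
            small_pdm.variances,
            rtol=1e-4,
        )

    def test_full_observation_recovers_coefficients(self, small_pdm):
        rng = np.random.default_rng(7)
        alpha0 = rng.normal(size=small_pdm.rank)
        inst = small_pdm.instance(alpha0)
        obs = PartialObservations(
            np.arange(small_pdm.n_vertices), inst.vertices, sigma2=1e-8
        )
        post = posterior(small_pdm, obs)
        m_alpha = small_pdm.project(post.model.mean_mesh())
        assert np.abs(m_alpha - alpha0).max() < 1e-3
        assert (
            np.abs(post.model.mean - inst.vertices.ravel()).max() < 1e-3
        )

    def test_posterior_variance_contracts_where_observed(self, small_pdm):
        rng = np.random.default_rng(3)
        idx = np.arange(0, 20)
        pts = small_pdm.mean.reshape(-1, 3)[idx] + rng.normal(
            scale=0.5, size=(len(idx), 3)
        )
        post = posterior(
            small_pdm, PartialObservations(idx, pts, sigma2=0.25)
        )

        def marginal_var(model, vertex):
            rows = model.basis[3 * vertex : 3 * vertex + 3]
            return float((rows**2 * model.variances).sum())

        prior_obs = marginal_var(small_pdm, 5)
        post_obs = marginal_var(post.model, 5)
        prior_far = marginal_var(small_pdm, 35)
        post_far = marginal_var(post.model, 35)
        assert post_obs < prior_obs
        # far-from-data vertices keep relatively more prior variance
        assert post_far / prior_far > post_obs / prior_obs

    def test_information_monotone_on_nested_observations(self, small_pdm):
        rng = np.random.default_rng(5)
        full_idx = np.arange(0, 30)
        pts = small_pdm.mean.reshape(-1, 3)[full_idx] + rng.normal(
            scale=0.3, size=(30, 3)
        )
        traces = []
        for k in (5, 15, 30):
            post = posterior(
                small_pdm,
                PartialObservations(full_idx[:k], pts[:k], sigma2=1.0),
            )
            traces.append(post.model.variances.sum())
        assert traces[0] >= traces[1] >= traces[2]

    def test_point_to_plane_requires_normals(self, small_pdm):
        obs = PartialObservations(
            np.array([0, 1, 2]), np.zeros((3, 3)), 1.0
        )
        with pytest.raises(ValueError):
            posterior(small_pdm, obs, point_to_plane=True)


class TestEstablishCorrespondence:
    def test_mean_matches_itself_fully(self, femur_pdm):
        obs = establish_partial_correspondence(
            femur_pdm, femur_pdm.mean_mesh(), accept_dist=5.0
        )
        assert len(obs) == femur_pdm.n_vertices
        assert (
            np.abs(obs.points - femur_pdm.mean.reshape(-1, 3)).max() < 1e-9
        )

    def test_ablated_mean_accepts_distal_fraction(self, femur_pdm):
        from femurssm.synthetic import ablate_proximal

        partial = ablate_proximal(femur_pdm.mean_mesh(), 0.25)
        obs = establish_partial_correspondence(
            femur_pdm, partial, accept_dist=5.0
        )
        # accepted fraction ~ the distal 75%, minus the band of matches
        # dropped at the damage rim
        frac = len(obs) / femur_pdm.n_vertices
        assert 0.60 <= frac <= 0.80
        # every rejected vertex lies in the proximal (removed) region
        v = femur_pdm.mean.reshape(-1, 3)
        z = v[:, 2]
        zcut = z.min() + 0.75 * np.ptp(z)
        rejected = np.setdiff1d(
            np.arange(femur_pdm.n_vertices), obs.indices
        )
        # rejections concentrate at the removed region and the rim band
        assert (z[rejected] > zcut - 15.0).all()
        stragglers = (z[rejected] <= zcut - 6.0).sum()
        assert stragglers < 0.01 * femur_pdm.n_vertices

    def test_zero_accept_distance_rejected(self, femur_pdm):
        from femurssm.mesh import RigidTransform, apply_rigid
        from femurssm.synthetic import ablate_proximal

        # shift the partial so no vertex is an exact hit: zero accept
        # distance then leaves no valid pairs
        partial = apply_rigid(
            ablate_proximal(femur_pdm.mean_mesh(), 0.4),
            RigidTransform(np.eye(3), np.array([0.05, 0.02, 0.01])),
        )
        with pytest.raises(ValueError, match="overlap"):
            establish_partial_correspondence(
                femur_pdm, partial, accept_dist=0.0
            )


class TestVariants:
    def _posterior(self, small_pdm):
        rng = np.random.default_rng(1)
        idx = np.arange(0, 25)
        pts = small_pdm.mean.reshape(-1, 3)[idx] + rng.normal(
            scale=0.3, size=(25, 3)
        )
        return posterior(
            small_pdm, PartialObservations(idx, pts, sigma2=1.0)
        )

    def test_level_zero_only(self, small_pdm):
        post = self._posterior(small_pdm)
        out = reconstruct_variants(post, levels=[0])
        assert len(out) == 1
        assert np.array_equal(
            out[0].vertices.ravel(), post.model.mean
        )

    def test_seven_default_variants_with_symmetry(self, small_pdm):
        post = self._posterior(small_pdm)
        out = reconstruct_variants(post)
        assert len(out) == 7
        mean = [v for v in out if v.name == "statrecon-mean"][0]
        plus1 = [v for v in out if v.name == "statrecon-+1sd"][0]
        minus1 = [v for v in out if v.name == "statrecon--1sd"][0]
        avg = 0.5 * (plus1.vertices + minus1.vertices)
        assert np.abs(avg - mean.vertices).max() < 1e-9


class TestStitch:
    def test_full_overlap_returns_mean(self, femur_pdm):
        obs = establish_partial_correspondence(
            femur_pdm, femur_pdm.mean_mesh(), accept_dist=5.0
        )
        post = posterior(femur_pdm, obs)
        out = stitch_reconstruction(post, femur_pdm.mean_mesh())
        assert (
            np.abs(out.vertices.ravel() - femur_pdm.mean).max() < 1e-6
        )

    def test_intact_vertices_end_on_partial_surface(self, femur_pdm):
        from femurssm.proximity import SurfaceQuery
        from femurssm.synthetic import ablate_proximal

        partial = ablate_proximal(femur_pdm.mean_mesh(), 0.25)
        obs = establish_partial_correspondence(
            femur_pdm, partial, accept_dist=5.0
        )
        post = posterior(femur_pdm, obs)
        out = stitch_reconstruction(post, partial, band=5.0)
        intact = post.intact
        d = SurfaceQuery(partial).distance(out.vertices[intact])
        assert d.max() < 5.0

    def test_zero_band_is_piecewise(self, femur_pdm):
        from femurssm.synthetic import ablate_proximal

        partial = ablate_proximal(femur_pdm.mean_mesh(), 0.25)
        obs = establish_partial_correspondence(
            femur_pdm, partial, accept_dist=5.0
        )
        post = posterior(femur_pdm, obs)
        out = stitch_reconstruction(post, partial, band=0.0)
        recon = ~post.intact
        # reconstructed side untouched: exactly the posterior mean
        assert np.array_equal(
            out.vertices[recon], post.model.mean.reshape(-1, 3)[recon]
        )
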