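"""Kaczmarz updates, TV functional/gradient and the full ART-TV solver."""

import numpy as np
import pytest

from epidmvct.art_tv import (ReconstructionConfig, art_update_ray,
                             nonneg_project, reconstruct, tv_gradient, tv_norm)
from epidmvct.geometry import (AcquisitionGeometry, RayPath, VolumeImage,
                               forward_project, trace_ray)
from epidmvct.phantom import build_thorax_phantom, default_thorax_spec
from epidmvct.preprocess import ProjectionImage
from epidmvct.simulate import simulate_epid_pair
from epidmvct.preprocess import preprocess_chain


def tv_norm_bruteforce(x, eps=0.0):
    """Literal evaluation of the TV sum over valid indices (oracle)."""
    total = 0.0
    for i in range(1, x.shape[0]):
        for j in range(1, x.shape[1]):
            total += np.sqrt((x[i, j] - x[i - 1, j]) ** 2
                             + (x[i, j] - x[i, j - 1]) ** 2 + eps)
    return total


class TestArtUpdateRay:
    def test_zero_residual_is_identity(self):
        x = np.array([[[1.0]], [[2.0]]])
        ray = RayPath(np.array([[0, 0, 0], [1, 0, 0]]), np.array([1.0, 1.0]))
        out = art_update_ray(x, ray, 3.0, 1.0)  # w.x = 3 = p
        np.testing.assert_array_equal(out, x)

    def test_hand_kaczmarz_step(self):
        """w = (1,1), p = 2, x = 0, lambda = 1 lands on (1,1) — the direct
        least-squares projection onto the hyperplane."""
        x = np.zeros((2, 1, 1))
        ray = RayPath(np.array([[0, 0, 0], [1, 0, 0]]), np.array([1.0, 1.0]))
        out = art_update_ray(x, ray, 2.0, 1.0)
        np.testing.assert_allclose(out.ravel(), [1.0, 1.0])
        # cross-check: projection of x onto {w.v = p} is x + (p - w.x) w/|w|^2
        w = np.array([1.0, 1.0])
        proj = (2.0 - 0.0) * w / np.dot(w, w)
        np.testing.assert_allclose(out.ravel(), proj)

    def test_empty_ray_is_noop(self):
        x = np.ones((2, 2, 2))
        out = art_update_ray(x, RayPath(np.empty((0, 3), int), np.empty(0)),
                             5.0, 0.5)
        np.testing.assert_array_equal(out, x)


class TestNonneg:
    def test_projection_cases(self):
        np.testing.assert_array_equal(nonneg_project(np.array([-1.0, 2.0])),
                                      [0.0, 2.0])
        x = np.array([0.5, 3.0])
        np.testing.assert_array_equal(nonneg_project(x), x)
        once = nonneg_project(np.array([-2.0, 0.1]))
        np.testing.assert_array_equal(nonneg_project(once), once)


class TestTV:
    def test_constant_image_zero(self):
        assert tv_norm(np.full((5, 7), 3.3)) == 0.0
        np.testing.assert_array_equal(tv_gradient(np.full((5, 7), 3.3)), 0.0)

    def test_corner_image_literal_sum(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert tv_norm(x) == pytest.approx(np.sqrt(2.0), abs=1e-15)
        assert tv_norm(x) == pytest.approx(tv_norm_bruteforce(x), abs=1e-15)

    def test_matches_bruteforce_random(self, rng):
        x = rng.random((6, 6))
        assert tv_norm(x) == pytest.approx(tv_norm_bruteforce(x), rel=1e-12)

    def test_positive_homogeneity(self, rng):
        x = rng.random((8, 8))
        for c in (2.0, -3.0, 0.5):
            assert tv_norm(c * x) == pytest.approx(abs(c) * tv_norm(x), rel=1e-12)

    def test_gradient_matches_numerical_differentiation(self, rng):
        """v agrees with central differences of the eps-smoothed TV."""
        eps = 1e-4
        x = rng.random((8, 8))
        v = tv_gradient(x, eps)
        h = 1e-6
        num = np.zeros_like(x)
        for i in range(8):
            for j in range(8):
                xp = x.copy(); xp[i, j] += h
                xm = x.copy(); xm[i, j] -= h
                num[i, j] = (tv_norm(xp, eps) - tv_norm(xm, eps)) / (2 * h)
        np.testing.assert_allclose(v, num, rtol=1e-4, atol=1e-8)

    def test_gradient_invariant_under_constant_shift(self, rng):
        x = rng.random((7, 5))
        np.testing.assert_allclose(tv_gradient(x), tv_gradient(x + 11.0),
                                   rtol=0, atol=1e-9)

    def test_volume_is_per_slice_sum(self, rng):
        vol = rng.random((6, 6, 4))
        total = sum(tv_norm(vol[:, :, k]) for k in range(4))
        assert tv_norm(vol) == pytest.approx(total, rel=1e-12)


def _parallel_projections(gt, geometry, angles, pitch):
    projs = []
    for a in angles:
        img = forward_project(gt, geometry, a, 1, geometry.detector_cols, pitch)
        projs.append(ProjectionImage(img, pitch, a))
    return projs


class TestReconstruct:
    def test_zero_projections_fixed_point(self, desk_geometry):
        projs = [ProjectionImage(np.zeros((20, 20)), 3.0, a)
                 for a in desk_geometry.gantry_angles]
        cfg = ReconstructionConfig(grid_shape=(8, 8, 4), voxel_size=(2, 2, 3),
                                   max_iterations=3)
        vol, trace = reconstruct(projs, desk_geometry, cfg)
        np.testing.assert_array_equal(vol.values, 0.0)

    def test_kaczmarz_converges_to_direct_solve(self, rng):
        """mu=0, lambda=1 on a consistent fully determined single-slice system:
        repeated sweeps approach the linear-algebra solution (oracle)."""
        n = 8
        pitch, ncols = 0.5, 24  # detector oversamples the voxel rows 2x
        geom = AcquisitionGeometry(sad=1000.0, sid=1540.0, beam="parallel",
                                   detector_rows=1, detector_cols=ncols,
                                   detector_pitch=pitch,
                                   gantry_angles=tuple(np.linspace(0, 180, 12,
                                                                   endpoint=False)))
        gt_vals = rng.random((n, n, 1)) * 0.01
        gt = VolumeImage.centered(gt_vals, (1.0, 1.0, 1.0))
        projs = _parallel_projections(gt, geom, geom.gantry_angles, pitch)
        # dense system matrix from the same exact ray tracer
        rows_w, rows_p = [], []
        for proj in projs:
            for c in range(ncols):
                path = trace_ray(geom, proj.gantry_angle, (0, c), gt,
                                 pitch=pitch, rows=1, cols=ncols)
                w = np.zeros(n * n)
                for (i, j, k), L in zip(path.indices, path.lengths):
                    w[i * n + j] += L
                rows_w.append(w)
                rows_p.append(proj.values[0, c])
        W = np.array(rows_w)
        p = np.array(rows_p)
        assert np.linalg.matrix_rank(W) == n * n  # fully determined
        direct, *_ = np.linalg.lstsq(W, p, rcond=None)
        cfg = ReconstructionConfig(grid_shape=(n, n, 1), voxel_size=(1, 1, 1),
                                   relaxation=1.0, tv_weight=0.0,
                                   max_iterations=200, stop_tol=1e-300)
        vol, _ = reconstruct(projs, geom, cfg)
        rel = (np.linalg.norm(vol.values.ravel() - direct)
               / np.linalg.norm(direct))
        assert rel < 1e-3

    def test_monotone_improvement_and_convergence(self, desk_geometry,
                                                  small_phantom):
        """Noiseless 10-view data: RMSE after 12 iterations beats iteration 1,
        and the relative change between iterations 11 and 12 is below 1%."""
        spec = default_thorax_spec(scale=0.2)
        projs = [preprocess_chain(*simulate_epid_pair(desk_geometry, a,
                                                      small_phantom))
                 for a in desk_geometry.gantry_angles]
        gt = build_thorax_phantom((32, 32, 8), (2.0, 2.0, 3.0), spec)

        def rmse_after(n_iter):
            cfg = ReconstructionConfig(grid_shape=(32, 32, 8),
                                       voxel_size=(2, 2, 3),
                                       max_iterations=n_iter)
            vol, trace = reconstruct(projs, desk_geometry, cfg)
            return np.sqrt(((vol.values - gt.values) ** 2).mean()), trace

        rmse1, _ = rmse_after(1)
        rmse12, trace = rmse_after(12)
        assert rmse12 < rmse1
        assert trace["rel_change"][11] < 0.01
        assert len(trace["iteration"]) == 12

    def test_nonnegativity_of_output(self, desk_geometry, small_phantom):
        projs = [preprocess_chain(*simulate_epid_pair(desk_geometry, a,
                                                      small_phantom))
                 for a in desk_geometry.gantry_angles[:3]]
        cfg = ReconstructionConfig(grid_shape=(16, 16, 4), voxel_size=(2, 2, 3),
                                   max_iterations=2)
        vol, _ = reconstruct(projs, desk_geometry, cfg)
        assert vol.values.min() >= 0.0

    def test_tv_regularization_smooths(self, desk_geometry, small_phantom):
        """Any positive TV weight yields a (much) smoother reconstruction than
        no regularization on noisy data, on every seed.  Between mu = 1 and
        mu = 5 the adaptive step mu*d overshoots and limit-cycles (the known
        large-weight non-convergence of this scheme), so only the
        regularized-vs-unregularized ordering is asserted."""
        for seed in (1, 2, 3):
            projs = [preprocess_chain(*simulate_epid_pair(
                desk_geometry, a, small_phantom, noise="poisson",
                seed=seed * 100 + i))
                for i, a in enumerate(desk_geometry.gantry_angles)]
            tvs = []
            for mu in (0.0, 1.0, 5.0):
                cfg = ReconstructionConfig(grid_shape=(32, 32, 8),
                                           voxel_size=(2, 2, 3),
                                           tv_weight=mu, max_iterations=6)
                vol, _ = reconstruct(projs, desk_geometry, cfg)
                tvs.append(tv_norm(vol.values))
            assert tvs[1] < tvs[0]
            assert tvs[2] < tvs[0]

    def test_deterministic_bit_identical(self, desk_geometry, small_phantom):
        projs = [preprocess_chain(*simulate_epid_pair(desk_geometry, a,
                                                      small_phantom))
                 for a in desk_geometry.gantry_angles[:4]]
        cfg = ReconstructionConfig(grid_shape=(16, 16, 4), voxel_size=(2, 2, 3),
                                   max_iterations=3)
        v1, t1 = reconstruct(projs, desk_geometry, cfg)
        v2, t2 = reconstruct(projs, desk_geometry, cfg)
        assert np.array_equal(v1.values, v2.values)
        assert t1 == t2

    def test_per_ray_cadence_small_problem(self, desk_geometry):
        """The literal per-ray TV cadence runs and stays non-negative."""
        vol = VolumeImage.centered(np.zeros((6, 6, 2)), (2, 2, 3))
        vol.values[1:5, 1:5, :] = 0.01
        o, t = simulate_epid_pair(desk_geometry, 0.0, vol, rows=9, cols=9,
                                  pitch=4.0)
        from epidmvct.preprocess import to_projection
        projs = [to_projection(o, t)]
        cfg = ReconstructionConfig(grid_shape=(6, 6, 2), voxel_size=(2, 2, 3),
                                   max_iterations=2, tv_cadence="per_ray")
        out, trace = reconstruct(projs, desk_geometry, cfg)
        assert out.values.min() >= 0.0
        assert len(trace["iteration"]) == 2

    def test_geometry_mismatch_rejected(self, desk_geometry):
        projs = [ProjectionImage(np.ones((10, 10)), 3.0, 0.0,
                                 center_uv=(1e6, 1e6))]
        cfg = ReconstructionConfig(grid_shape=(8, 8, 4), voxel_size=(2, 2, 3))
        with pytest.raises(ValueError, match="geometry mismatch"):
            reconstruct(projs, desk_geometry, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReconstructionConfig(relaxation=2.5)
        with pytest.raises(ValueError):
            ReconstructionConfig(max_iterations=0)
        with pytest.raises(ValueError):
            ReconstructionConfig(tv_cadence="sometimes")
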