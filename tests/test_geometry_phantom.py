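"""Ray tracing, phantom construction and EPID simulation."""

import numpy as np
import pytest

from epidmvct.geometry import (AcquisitionGeometry, CouchShift, VolumeImage,
                               forward_project, ray_endpoints, shift_volume,
                               trace_ray)
from epidmvct.phantom import Insert, build_thorax_phantom, default_thorax_spec
from epidmvct.simulate import simulate_epid_pair


def dense_line_integral(volume, p0, p1, n=10000):
    """Independent oracle: midpoint-rule sampling of the line integral,
    restricted to the segment crossing the volume's bounding box."""
    lo = np.asarray(volume.origin)
    hi = lo + np.array(volume.values.shape) * np.asarray(volume.voxel_size)
    d = p1 - p0
    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        if d[ax] != 0:
            t1, t2 = (lo[ax] - p0[ax]) / d[ax], (hi[ax] - p0[ax]) / d[ax]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    if tmax <= tmin:
        return 0.0
    p0, p1 = p0 + tmin * d, p0 + tmax * d
    ts = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    idx = np.floor((pts - np.asarray(volume.origin)) /
                   np.asarray(volume.voxel_size)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(volume.values.shape)), axis=1)
    vals = np.zeros(n)
    vals[inside] = volume.values[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    seg = np.linalg.norm(p1 - p0) / n
    return float(vals.sum() * seg)


class TestTraceRay:
    def test_central_ray_through_cube(self, cube_volume):
        geom = AcquisitionGeometry(detector_rows=11, detector_cols=11,
                                   detector_pitch=1.0)
        path = trace_ray(geom, 0.0, (5, 5), cube_volume)
        assert abs(path.lengths.sum() - 20.0) < 1e-6
        assert abs(path.raysum(cube_volume) - 0.2) < 1e-6

    def test_oblique_rays_match_dense_sampling(self, cube_volume, rng):
        geom = AcquisitionGeometry(detector_rows=64, detector_cols=64,
                                   detector_pitch=2.0)
        for pixel in [(3, 7), (60, 2), (31, 33), (0, 63)]:
            path = trace_ray(geom, 33.0, pixel, cube_volume)
            p0, p1 = ray_endpoints(geom, 33.0, 64, 64, 2.0)
            k = pixel[0] * 64 + pixel[1]
            oracle = dense_line_integral(cube_volume, p0[k], p1[k])
            got = path.raysum(cube_volume)
            assert got == pytest.approx(oracle, rel=1e-3, abs=1e-6)

    def test_ray_missing_volume_is_empty(self, cube_volume):
        geom = AcquisitionGeometry(detector_rows=300, detector_cols=300,
                                   detector_pitch=10.0)
        # extreme corner pixel: ray passes far outside the 20 mm cube
        path = trace_ray(geom, 0.0, (0, 0), cube_volume)
        assert len(path) == 0
        assert path.raysum(cube_volume) == 0.0

    def test_pixel_outside_grid_rejected(self, cube_volume):
        geom = AcquisitionGeometry(detector_rows=8, detector_cols=8,
                                   detector_pitch=1.0)
        with pytest.raises(ValueError, match="outside"):
            trace_ray(geom, 0.0, (8, 0), cube_volume)

    def test_raysum_linearity(self, rng):
        a = VolumeImage.centered(rng.random((9, 9, 9)) * 0.01, (2, 2, 2))
        b = VolumeImage.centered(rng.random((9, 9, 9)) * 0.01, (2, 2, 2))
        ab = VolumeImage.centered(a.values + b.values, (2, 2, 2))
        geom = AcquisitionGeometry(detector_rows=16, detector_cols=16,
                                   detector_pitch=2.0)
        for angle in (0.0, 45.0, 117.0):
            ra = forward_project(a, geom, angle, 16, 16, 2.0)
            rb = forward_project(b, geom, angle, 16, 16, 2.0)
            rab = forward_project(ab, geom, angle, 16, 16, 2.0)
            np.testing.assert_allclose(rab, ra + rb, atol=1e-9)

    def test_shift_consistency(self, rng):
        """Translating the phantom equals counter-translating the rays.

        The phantom support stays interior so the translation clips nothing."""
        vals = np.zeros((20, 20, 10))
        vals[4:-4, 4:-4, 2:-2] = rng.random((12, 12, 6)) * 0.01
        vol = VolumeImage.centered(vals, (2, 2, 2))
        geom = AcquisitionGeometry(detector_rows=24, detector_cols=24,
                                   detector_pitch=3.0)
        delta = np.array([4.0, -2.0, 2.0])  # grid-aligned: trilinear is exact
        shifted = shift_volume(vol, CouchShift(*delta))
        p0, p1 = ray_endpoints(geom, 36.0, 24, 24, 3.0)
        direct = np.empty(p0.shape[0])
        counter = np.empty(p0.shape[0])
        from epidmvct._kernels import forward_raysums
        forward_raysums(shifted.values, *vol.origin, *vol.voxel_size,
                        p0, p1, direct)
        forward_raysums(vol.values, *vol.origin, *vol.voxel_size,
                        np.ascontiguousarray(p0 - delta),
                        np.ascontiguousarray(p1 - delta), counter)
        np.testing.assert_allclose(direct, counter, atol=1e-6)

    def test_magnification(self):
        """A point insert at the isocenter projects with scale SID/SAD."""
        geom = AcquisitionGeometry(detector_rows=129, detector_cols=129,
                                   detector_pitch=1.0)
        vol = VolumeImage.centered(np.zeros((81, 81, 3)), (1.0, 1.0, 1.0))
        vol.values[40 + 20, 40, 1] = 1.0  # 20 mm off-axis along +x
        img = forward_project(vol, geom, 0.0, 129, 129, 1.0)
        r, c = np.unravel_index(np.argmax(img), img.shape)
        u = (c - 64) * 1.0
        assert abs(u - 20.0 * geom.magnification) <= 1.0  # within one pixel
        assert abs(r - 64) <= 1


class TestPhantom:
    def test_single_water_ellipse_piecewise_constant(self):
        spec = [Insert("ellipsoid", (0, 0, 0), (30, 20, 10), 0.005, "water")]
        vol = build_thorax_phantom((40, 40, 12), (2.0, 2.0, 2.0), spec)
        x = vol.voxel_centers(0)[:, None, None]
        y = vol.voxel_centers(1)[None, :, None]
        z = vol.voxel_centers(2)[None, None, :]
        inside = (x / 30) ** 2 + (y / 20) ** 2 + (z / 10) ** 2 <= 1
        assert np.all(vol.values[inside] == 0.005)
        assert np.all(vol.values[~inside] == 0.0)

    def test_tissue_ordering(self):
        vol = build_thorax_phantom((128, 128, 16), (2.0, 2.0, 3.0),
                                   default_thorax_spec(scale=0.5))
        lung = vol.values[np.isclose(vol.values, 0.0013)]
        body = vol.values[np.isclose(vol.values, 0.0049)]
        spine = vol.values[np.isclose(vol.values, 0.0085)]
        assert lung.size and body.size and spine.size
        assert lung.max() < body.min() < spine.min()

    def test_determinism(self):
        spec = default_thorax_spec(scale=0.5)
        a = build_thorax_phantom((64, 64, 8), (2, 2, 3), spec)
        b = build_thorax_phantom((64, 64, 8), (2, 2, 3), spec)
        assert np.array_equal(a.values, b.values)

    def test_insert_outside_grid_rejected(self):
        spec = [Insert("sphere", (500, 0, 0), (5,), 0.005, "stray")]
        with pytest.raises(ValueError, match="stray"):
            build_thorax_phantom((32, 32, 8), (2, 2, 3), spec)


class TestSimulateEpidPair:
    def test_empty_phantom_transmission_equals_open(self, desk_geometry):
        empty = VolumeImage.centered(np.zeros((16, 16, 4)), (2, 2, 3))
        o, t = simulate_epid_pair(desk_geometry, 18.0, empty,
                                  rows=64, cols=64, pitch=4.0)
        np.testing.assert_array_equal(o.values, t.values)

    def test_uniform_slab_beer_lambert(self):
        """Central perpendicular ray: transmission/open = exp(−μL)."""
        mu, L = 0.007, 100.0
        slab = VolumeImage.centered(np.full((60, 50, 20), mu), (2.0, L / 50, 3.0))
        geom = AcquisitionGeometry(detector_rows=33, detector_cols=33,
                                   detector_pitch=2.0)
        o, t = simulate_epid_pair(geom, 0.0, slab)
        ratio = t.values[16, 16] / o.values[16, 16]
        assert ratio == pytest.approx(np.exp(-mu * L), rel=1e-9)

    def test_symmetric_phantom_symmetric_image(self):
        spec = default_thorax_spec(scale=0.2, lesion=False)  # left-right symmetric
        vol = build_thorax_phantom((129, 129, 8), (1.0, 1.0, 3.0), spec)
        geom = AcquisitionGeometry(detector_rows=65, detector_cols=65,
                                   detector_pitch=2.0)
        _, t = simulate_epid_pair(geom, 0.0, vol)
        np.testing.assert_allclose(t.values, t.values[:, ::-1], atol=1e-9)

    def test_poisson_mean_matches_noiseless(self, desk_geometry):
        """Sample mean of ~10^4 i.i.d. pixels within 3 SE of the mean."""
        empty = VolumeImage.centered(np.zeros((4, 4, 4)), (2, 2, 2))
        o, _ = simulate_epid_pair(desk_geometry, 0.0, empty, i0_level=1000.0,
                                  noise="poisson", seed=7,
                                  rows=120, cols=120, pitch=2.0)
        from epidmvct.simulate import field_aperture_mask
        mask = field_aperture_mask(desk_geometry, 120, 120, 2.0)
        samples = o.values[mask]
        n = samples.size
        assert n > 9000
        se = np.sqrt(1000.0 / n)
        assert abs(samples.mean() - 1000.0) < 3 * se

    def test_nonpositive_i0_rejected(self, desk_geometry, cube_volume):
        with pytest.raises(ValueError, match="i0_level"):
            simulate_epid_pair(desk_geometry, 0.0, cube_volume, i0_level=0.0)
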