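"""Projector, backprojector and FBP: adjointness, linearity, quantitativeness."""

import numpy as np
import pytest
from scipy import ndimage

from n2itomo.geometry import (
    ImageSlice,
    ProjectionGeometry,
    Sinogram,
    backproject,
    fbp_reconstruct,
    forward_project,
    make_geometry,
    operator_norm,
    system_matrix,
)


def ray_oracle(img, theta, t_offsets, n_sub=1000):
    """Brute-force line integrals: dense sub-sampling of the bilinearly
    interpolated image along each ray."""
    N = img.shape[0]
    c = (N - 1) / 2.0
    L = N * 0.75
    tau = np.linspace(-L, L, n_sub)
    dtau = tau[1] - tau[0]
    d = np.array([np.cos(theta), np.sin(theta)])
    e = np.array([-np.sin(theta), np.cos(theta)])
    out = []
    for t in t_offsets:
        pts = t * e[:, None] + tau[None, :] * d[:, None] + c
        vals = ndimage.map_coordinates(img, pts, order=1, cval=0.0)
        out.append(vals.sum() * dtau)
    return np.array(out)


class TestMakeGeometry:
    @pytest.mark.parametrize(
        "n,rng_,offset,expected",
        [
            (4, np.pi, 0.0, [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]),
            (1, 2 * np.pi, 0.1, [0.1]),
        ],
    )
    def test_equally_spaced(self, n, rng_, offset, expected):
        geom = make_geometry(n, rng_, offset, 32, 32)
        np.testing.assert_allclose(geom.angles, expected, atol=1e-12)

    def test_full_turn_sampling(self):
        geom = make_geometry(300, 2 * np.pi, 0.0, 128, 128)
        assert geom.num_angles == 300
        gaps = np.diff(geom.angles)
        np.testing.assert_allclose(gaps, 2 * np.pi / 300, atol=1e-12)

    @pytest.mark.parametrize("bad", [dict(num_angles=0), dict(image_size=-4)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(num_angles=4, angular_range=np.pi, offset=0.0,
                      num_detector_pixels=16, image_size=16)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_geometry(**kwargs)

    def test_duplicate_angles_rejected(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(angles=[0.0, 0.0], num_detector_pixels=8, image_size=8)


class TestForwardProject:
    def test_zero_image_gives_zero_sinogram(self):
        geom = make_geometry(8, np.pi, 0.0, 32, 32)
        sino = forward_project(ImageSlice(np.zeros((32, 32))), geom)
        assert np.all(sino.values == 0)

    def test_disk_chord_length(self):
        N = 64
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        disk = ((ii - c) ** 2 + (jj - c) ** 2 <= 20**2).astype(float)
        geom = make_geometry(12, np.pi, 0.0, N, N)
        sino = forward_project(ImageSlice(disk), geom)
        central = sino.values[:, N // 2 - 1 : N // 2 + 1].mean(axis=1)
        # central ray crosses the full diameter: chord length 2r = 40
        np.testing.assert_allclose(central, 40.0, rtol=0.02)

    def test_matches_dense_ray_oracle_on_smooth_image(self):
        N = 33
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        img = np.exp(-(((ii - c) / 5.0) ** 2 + ((jj - c) / 7.0) ** 2))
        geom = make_geometry(7, np.pi, 0.15, N, N)
        sino = forward_project(ImageSlice(img), geom)
        for a, theta in enumerate(geom.angles):
            t = (np.arange(N) - geom.rotation_center)[8:-8]
            expected = ray_oracle(img, theta, t)
            np.testing.assert_allclose(sino.values[a, 8:-8], expected, atol=0.02 * expected.max())

    def test_unit_center_pixel_axis_aligned(self):
        N = 33
        img = np.zeros((N, N))
        img[N // 2, N // 2] = 1.0
        geom = make_geometry(2, np.pi, 0.0, N, N)  # angles 0 and pi/2
        sino = forward_project(ImageSlice(img), geom)
        np.testing.assert_allclose(sino.values[:, N // 2], 1.0, atol=1e-9)

    def test_size_mismatch_raises(self):
        geom = make_geometry(4, np.pi, 0.0, 16, 16)
        with pytest.raises(ValueError):
            forward_project(ImageSlice(np.zeros((32, 32))), geom)


class TestBackproject:
    def test_zero_sinogram_gives_zero_image(self):
        geom = make_geometry(6, np.pi, 0.0, 16, 16)
        img = backproject(Sinogram(np.zeros((6, 16)), geom))
        assert np.all(img.values == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjoint_identity(self, seed):
        rng = np.random.default_rng(seed)
        geom = make_geometry(23, np.pi, 0.31, 32, 32)
        x = rng.standard_normal((32, 32))
        y = rng.standard_normal((23, 32))
        Ax = forward_project(ImageSlice(x), geom).values
        Aty = backproject(Sinogram(y, geom)).values
        lhs = float(np.sum(Ax * y))
        rhs = float(np.sum(x * Aty))
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_single_angle_backprojection_constant_along_rays(self):
        N = 32
        geom = make_geometry(1, np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        sino = Sinogram(rng.random((1, N)), geom)
        img = backproject(sino).values
        # angle 0: rays run along axis 0, so columns are constant (away from
        # edges where the interpolation weight pattern differs)
        interior = img[4:-4, 4:-4]
        assert np.max(np.abs(interior - interior[0])) < 1e-9


class TestFBP:
    def test_linear_in_sinogram(self, rng):
        geom = make_geometry(24, np.pi, 0.0, 32, 32)
        y1 = rng.standard_normal((24, 32))
        y2 = rng.standard_normal((24, 32))
        a, b = 1.7, -0.4
        r = fbp_reconstruct(Sinogram(a * y1 + b * y2, geom)).values
        r1 = fbp_reconstruct(Sinogram(y1, geom)).values
        r2 = fbp_reconstruct(Sinogram(y2, geom)).values
        scale = np.abs(a * r1 + b * r2).max()
        assert np.max(np.abs(r - a * r1 - b * r2)) <= 1e-8 * scale

    def test_zero_sinogram(self):
        geom = make_geometry(8, np.pi, 0.0, 16, 16)
        assert np.all(fbp_reconstruct(Sinogram(np.zeros((8, 16)), geom)).values == 0)

    @pytest.mark.parametrize("filter_name", ["ram-lak", "shepp-logan", "cosine"])
    def test_disk_interior_value_recovered(self, filter_name):
        N = 128
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        disk = ((ii - c) ** 2 + (jj - c) ** 2 <= 40**2).astype(float)
        geom = make_geometry(256, np.pi, 0.0, N, N)
        sino = forward_project(ImageSlice(disk), geom)
        rec = fbp_reconstruct(sino, filter_name).values
        interior = (ii - c) ** 2 + (jj - c) ** 2 <= 37**2
        assert abs(rec[interior].mean() - 1.0) < 0.05

    def test_matches_reference_fbp_implementation(self):
        """Interior of a disk reconstruction agrees with scikit-image's iradon."""
        from skimage.transform import iradon

        N = 128
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        disk = ((ii - c) ** 2 + (jj - c) ** 2 <= 40**2).astype(float)
        geom = make_geometry(256, np.pi, 0.0, N, N)
        sino = forward_project(ImageSlice(disk), geom)
        ours = fbp_reconstruct(sino).values
        ref = iradon(
            sino.values.T,
            theta=np.degrees(geom.angles),
            filter_name="ramp",
            circle=False,
            output_size=N,
        )
        interior = (ii - c) ** 2 + (jj - c) ** 2 <= 37**2
        assert np.sqrt(np.mean((ours - ref)[interior] ** 2)) < 0.03

    def test_reconstruct_project_near_identity_on_smooth_phantom(self):
        N = 64
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        img = np.exp(-(((ii - c) / 10.0) ** 2 + ((jj - c) / 14.0) ** 2))
        geom = make_geometry(2 * N, np.pi, 0.0, N, N)
        rec = fbp_reconstruct(forward_project(ImageSlice(img), geom)).values
        assert np.linalg.norm(rec - img) / np.linalg.norm(img) <= 0.10

    def test_unknown_filter_rejected(self):
        geom = make_geometry(8, np.pi, 0.0, 16, 16)
        with pytest.raises(ValueError):
            fbp_reconstruct(Sinogram(np.zeros((8, 16)), geom), "hann")


class TestOperatorNorm:
    def test_matches_dense_svd(self):
        geom = make_geometry(24, np.pi, 0.0, 16, 16)
        sv_max = np.linalg.svd(system_matrix(geom).toarray(), compute_uv=False)[0]
        est = operator_norm(geom, iterations=100, seed=1)
        assert abs(est - sv_max) <= 0.01 * sv_max

    def test_nondecreasing_in_iterations(self):
        geom = make_geometry(12, np.pi, 0.0, 16, 16)
        ests = [operator_norm(geom, iterations=k, seed=7) for k in (1, 3, 10, 30)]
        assert all(b >= a - 1e-9 for a, b in zip(ests, ests[1:]))

    def test_deterministic_given_seed(self):
        geom = make_geometry(12, np.pi, 0.0, 16, 16)
        assert operator_norm(geom, 20, seed=3) == operator_norm(geom, 20, seed=3)
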