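"""Gridding reconstruction, Cartesian FFT route, velocity maps, SNR."""

import numpy as np
import pytest

from flow4d import (
    GriddingConfig,
    PhantomSpec,
    SequenceParams,
    compute_snr,
    design_spiral_interleaf,
    grid_reconstruct,
    make_phantom,
    phase_difference_velocity,
)
from flow4d.acquire import acquisition_grid, object_snapshot
from flow4d.gating import BinnedKSpace
from flow4d.recon import cartesian_reconstruct, radial_density_weights, _grid_plane


def _binned_from_planes(data, rr=900.0):
    nf, nseg, nkz, nl = data.shape[:4]
    return BinnedKSpace(
        data=data, counts=np.ones((nf, nseg, nkz, nl), int),
        rr_mean=rr, t_sys=320.0, fill_fraction=1.0, n_borrowed=0,
    )


def _spiral_kspace_of_image(img, traj, grid):
    """Exact NUDFT of a gridded object at the stack-of-spirals samples."""
    xs, ys, zs = grid.axis_coords(0), grid.axis_coords(1), grid.axis_coords(2)
    nx, ny = len(xs), len(ys)
    W = np.tensordot(img, np.exp(-2j * np.pi * np.outer(zs, traj.kz)), axes=(2, 0))
    kx, ky = traj.kx.ravel(), traj.ky.ravel()
    E = np.exp(
        -2j * np.pi * (np.outer(kx, np.repeat(xs, ny)) + np.outer(ky, np.tile(ys, nx)))
    )
    out = np.empty((traj.n_slice_encodes, traj.n_lines, traj.n_samples), complex)
    for zi in range(traj.n_slice_encodes):
        out[zi] = (E @ W[:, :, zi].ravel()).reshape(traj.n_lines, traj.n_samples)
    return out


@pytest.fixture(scope="module")
def small_phantom_kspace(small_spec, small_params, small_traj):
    field = make_phantom(small_spec)
    agrid = acquisition_grid(small_params)
    n_kz, n_l, n_s = (
        small_traj.n_slice_encodes, small_traj.n_lines, small_traj.n_samples,
    )
    data = np.zeros((1, 4, n_kz, n_l, n_s), complex)
    imgs = {}
    for seg in range(4):
        img = object_snapshot(field, agrid, 160.0, 900.0, seg, small_params.venc)
        imgs[seg] = img
        data[0, seg] = _spiral_kspace_of_image(img, small_traj, agrid)
    return field, agrid, imgs, _binned_from_planes(data)


class TestGridding:
    def test_point_spread_function(self, small_params, small_traj):
        """Point object at the volume center: peak there, sidelobes low."""
        n_kz, n_l, n_s = (
            small_traj.n_slice_encodes, small_traj.n_lines, small_traj.n_samples,
        )
        r0 = np.array([1.4, 1.4, 2.5])  # a voxel center adjacent to the origin
        data = np.zeros((1, 4, n_kz, n_l, n_s), complex)
        for zi in range(n_kz):
            for li in range(n_l):
                kx, ky = small_traj.line_samples(li)
                ph = np.exp(
                    -2j * np.pi * (kx * r0[0] + ky * r0[1] + small_traj.kz[zi] * r0[2])
                )
                data[0, :, zi, li] = ph
        img = grid_reconstruct(_binned_from_planes(data), small_traj, small_params)
        mag = np.abs(img[0, 0])
        peak = np.unravel_index(mag.argmax(), mag.shape)
        assert peak == (16, 16, 2)
        side = mag.copy()
        side[peak[0] - 1 : peak[0] + 2, peak[1] - 1 : peak[1] + 2, :] = 0.0
        assert mag[peak] / side.max() > 10.0

    def test_gridding_matches_direct_adjoint_dft_oracle(self, small_phantom_kspace,
                                                        small_params, small_traj):
        """Gridding vs the directly evaluated (brute-force) density-compensated
        inverse DFT on the 32^2 grid: the kernel interpolation error only."""
        field, agrid, imgs, binned = small_phantom_kspace
        rec = grid_reconstruct(binned, small_traj, small_params)[0, 0]
        wts = radial_density_weights(small_traj).ravel()
        xs, ys, zs = agrid.axis_coords(0), agrid.axis_coords(1), agrid.axis_coords(2)
        kx, ky = small_traj.kx.ravel(), small_traj.ky.ravel()
        E = np.exp(
            -2j * np.pi
            * (np.outer(kx, np.repeat(xs, 32)) + np.outer(ky, np.tile(ys, 32)))
        )
        n_kz = small_traj.n_slice_encodes
        n_rec = small_params.n_slices_recon
        Wadj = np.zeros((32, 32, n_kz), complex)
        for zi in range(n_kz):
            Wadj[:, :, zi] = (
                E.conj().T @ (wts * binned.data[0, 0, zi].ravel())
            ).reshape(32, 32) * small_params.voxel_size**2
        lo = (n_kz - n_rec) // 2
        fz = np.exp(2j * np.pi * np.outer(small_traj.kz, zs[lo : lo + n_rec])) / n_kz
        oracle = np.tensordot(Wadj, fz, axes=(2, 0))
        nrmse = np.linalg.norm(np.abs(rec) - np.abs(oracle)) / np.linalg.norm(
            np.abs(oracle)
        )
        assert nrmse < 0.05

    def test_linearity(self, small_phantom_kspace, small_params, small_traj):
        field, agrid, imgs, binned = small_phantom_kspace
        rng = np.random.default_rng(0)
        other = binned.data * 0 + (
            rng.normal(size=binned.data.shape) + 1j * rng.normal(size=binned.data.shape)
        )
        a = grid_reconstruct(binned, small_traj, small_params)
        b = grid_reconstruct(_binned_from_planes(other), small_traj, small_params)
        ab = grid_reconstruct(_binned_from_planes(binned.data + other),
                              small_traj, small_params)
        scale = np.abs(ab).max()
        assert np.abs(ab - (a + b)).max() <= 1e-8 * scale

    def test_voronoi_weights_also_reconstruct(self, small_phantom_kspace,
                                              small_params, small_traj):
        field, agrid, imgs, binned = small_phantom_kspace
        rec_a = grid_reconstruct(binned, small_traj, small_params)
        rec_v = grid_reconstruct(
            binned, small_traj, small_params,
            GriddingConfig(density_compensation="voronoi"),
        )
        # both give comparable magnitude images of the same object
        na = np.abs(rec_a[0, 0]); nv = np.abs(rec_v[0, 0])
        assert np.linalg.norm(na - nv) / np.linalg.norm(na) < 0.1

    def test_mismatched_layout_raises(self, small_phantom_kspace, small_params):
        field, agrid, imgs, binned = small_phantom_kspace
        bad = design_spiral_interleaf(
            SequenceParams(fov=(89.6, 89.6), matrix=(32, 32), n_interleaves=8,
                           n_slices_recon=4, slice_thickness=5.0)
        )
        with pytest.raises(ValueError):
            grid_reconstruct(binned, bad, small_params)


class TestCartesianRoute:
    def test_equals_inverse_dft_exactly(self):
        """Fully sampled Cartesian k-space degenerates to the exact inverse DFT."""
        p = SequenceParams(fov=(44.8, 44.8), matrix=(16, 16), n_slices_recon=4,
                           slice_oversampling=0.0, slice_thickness=5.0)
        rng = np.random.default_rng(1)
        ks = rng.normal(size=(16, 16, 4)) + 1j * rng.normal(size=(16, 16, 4))
        img = cartesian_reconstruct(ks, p)
        xs = (np.arange(16) + 0.5 - 8) * 2.8
        kv = (np.arange(16) - 8) / 44.8
        zc = (np.arange(4) + 0.5 - 2) * 5.0
        kzv = (np.arange(4) - 2) / 20.0
        ex = np.exp(2j * np.pi * np.outer(kv, xs))
        ez = np.exp(2j * np.pi * np.outer(kzv, zc))
        oracle = np.einsum("abc,ai,bj,ck->ijk", ks, ex, ex, ez) / (16 * 16 * 4)
        assert np.abs(img - oracle).max() < 1e-10 * np.abs(oracle).max()


class TestVelocityMaps:
    def test_identical_segments_give_zero_velocity(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(2, 1, 4, 4, 2)) + 1j * rng.normal(size=(2, 1, 4, 4, 2))
        segs = np.repeat(s, 4, axis=1)
        series = phase_difference_velocity(segs, 120.0, (2.8, 2.8, 2.8), 45.0)
        np.testing.assert_allclose(series.velocity, 0.0, atol=1e-14)
        np.testing.assert_allclose(series.magnitude, np.abs(s[:, 0]))

    def test_pi_phase_maps_to_venc(self):
        segs = np.ones((1, 4, 2, 2, 1), complex)
        segs[0, 1] = np.exp(1j * np.pi * 0.999999)
        series = phase_difference_velocity(segs, 120.0, (1, 1, 1), 45.0)
        assert series.velocity[0, 0, 0, 0, 0] == pytest.approx(1.20, abs=1e-4)

    def test_velocity_antisymmetry(self):
        rng = np.random.default_rng(3)
        segs = np.exp(1j * rng.uniform(-2, 2, (1, 4, 3, 3, 2)))
        neg = segs.copy()
        neg[:, 1:] = np.conj(segs[:, 1:]) * segs[:, :1] ** 2  # negate encoded phase
        a = phase_difference_velocity(segs, 120.0, (1, 1, 1), 45.0)
        b = phase_difference_velocity(neg, 120.0, (1, 1, 1), 45.0)
        np.testing.assert_allclose(b.velocity, -a.velocity, atol=1e-12)

    def test_end_to_end_uniform_half_meter_per_second(self, small_spec, small_params,
                                                      small_traj):
        """Uniform 0.5 m/s object through the whole chain, noise free."""
        from flow4d import GatingConfig, bin_samples, sample_rr_intervals, \
            simulate_acquisition
        from tests.test_acquire import _UniformVelocityField

        field = _UniformVelocityField(small_spec, v=(0.5, 0.0, 0.0))
        rr = sample_rr_intervals(900.0, 0.0, 400, seed=1)
        ss = simulate_acquisition(field, small_traj, small_params, rr, seed=2)
        binned = bin_samples(ss, GatingConfig(n_frames=4))
        imgs = grid_reconstruct(binned, small_traj, small_params)
        series = phase_difference_velocity(
            imgs, small_params.venc, (2.8, 2.8, 5.0), binned.frame_duration
        )
        assert np.abs(series.velocity[:, 0] - 0.5).max() < 0.01
        assert np.abs(series.velocity[:, 1:]).max() < 0.01


class TestSNR:
    def test_constant_cases(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 1.0, (16, 16, 4))
        noise = (noise - noise.mean()) / noise.std()  # SD exactly 1
        mag = np.full((16, 16, 4), 10.0)
        roi = np.ones_like(mag, bool)
        mean, sd = compute_snr(mag, noise, roi)
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0, abs=1e-12)
        mean2, _ = compute_snr(mag, noise * 2, roi)
        assert mean2 == pytest.approx(5.0)

    def test_simulated_phantom_snr_within_five_percent(self):
        rng = np.random.default_rng(5)
        signal, noise_sd = 7.3, 0.21
        mag = signal + rng.normal(0, noise_sd, (32, 32, 8))
        noise = rng.normal(0, noise_sd, (32, 32, 8))
        roi = np.zeros(mag.shape, bool)
        roi[8:24, 8:24, 2:6] = True
        mean, _ = compute_snr(mag, noise, roi)
        assert mean == pytest.approx(signal / noise_sd, rel=0.05)

    def test_zero_noise_error(self):
        with pytest.raises(ValueError):
            compute_snr(np.ones((4, 4, 1)), np.zeros((4, 4, 1)), np.ones((4, 4, 1), bool))
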