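"""Acquisition simulator: signal model oracles, navigator, scan-time accounting."""

import numpy as np
import pytest

from flow4d import (
    AcquisitionError,
    NavigatorConfig,
    PhantomSpec,
    RespiratoryTrace,
    actual_scan_time,
    make_phantom,
    navigator_accept,
    sample_rr_intervals,
    simulate_acquisition,
)
from flow4d.acquire import acquisition_grid, nudft_samples, object_snapshot
from flow4d.phantom import AnalyticFlowField


class _UniformVelocityField(AnalyticFlowField):
    """Uniform magnitude everywhere, constant velocity: synthetic test object."""

    def __init__(self, spec, v=(0.0, 0.0, 0.0)):
        super().__init__(spec)
        self._v = np.asarray(v, dtype=float)

    def magnitude(self, points):
        return np.ones(np.atleast_2d(points).shape[0])

    def fluid_mask(self, points):
        return np.ones(np.atleast_2d(points).shape[0], dtype=bool)

    def static_mask(self, points):
        return np.zeros(np.atleast_2d(points).shape[0], dtype=bool)

    def velocity(self, points, t, rr=None):
        return np.broadcast_to(self._v, (np.atleast_2d(points).shape[0], 3)).copy()


def _simulate_small(small_spec, small_params, small_traj, field=None, **kw):
    f = field or make_phantom(small_spec)
    rr = sample_rr_intervals(f.spec.rr_mean_ms, f.spec.rr_sd_ms, 400, seed=1)
    return simulate_acquisition(f, small_traj, small_params, rr, seed=2, **kw)


class TestSignalModel:
    def test_dc_sample_equals_sum_of_magnitudes(
        self, small_spec, small_params, small_traj
    ):
        field = _UniformVelocityField(small_spec)
        ss = _simulate_small(small_spec, small_params, small_traj, field=field)
        grid = acquisition_grid(small_params)
        total = field.magnitude(grid.points()).sum()
        kz0 = np.argmin(np.abs(small_traj.kz))
        for ev, row in zip(ss.events, ss.samples):
            if ev.segment == 0 and ev.slice_encode == kz0:
                assert abs(row[0] - total) <= 1e-6 * abs(total)
                break
        else:
            pytest.fail("no reference readout at the central slice encode")

    def test_samples_match_direct_dft_oracle(self, small_spec, small_params, small_traj):
        ss = _simulate_small(small_spec, small_params, small_traj)
        grid = acquisition_grid(small_params)
        field = make_phantom(small_spec)
        rng = np.random.default_rng(3)
        picks = rng.choice(ss.n_events, size=10, replace=False)
        for i in picks:
            ev = ss.events[i]
            img = object_snapshot(
                field, grid, ev.t_since_r, ev.rr, ev.segment, small_params.venc
            )
            kx, ky = small_traj.line_samples(ev.line)
            sel = rng.choice(small_traj.n_samples, size=5, replace=False)
            oracle = nudft_samples(
                img, grid, kx[sel], ky[sel], small_traj.kz[ev.slice_encode]
            )
            scale = np.abs(oracle).max()
            assert np.abs(ss.samples[i][sel] - oracle).max() <= 1e-5 * scale

    def test_constant_velocity_encodes_expected_phase(
        self, small_spec, small_params, small_traj
    ):
        """v = 0.6 m/s along x at venc 120 cm/s -> vx phase pi/2 after recon."""
        from flow4d import GatingConfig, bin_samples, grid_reconstruct

        field = _UniformVelocityField(small_spec, v=(0.6, 0.0, 0.0))
        ss = _simulate_small(small_spec, small_params, small_traj, field=field)
        binned = bin_samples(ss, GatingConfig(n_frames=2))
        imgs = grid_reconstruct(binned, small_traj, small_params)
        phase = np.angle(imgs[0, 1] * np.conj(imgs[0, 0]))
        np.testing.assert_allclose(phase, np.pi / 2, atol=1e-6)
        phase_ref = np.angle(imgs[0, 2] * np.conj(imgs[0, 0]))
        np.testing.assert_allclose(phase_ref, 0.0, atol=1e-6)

    def test_bit_identical_under_seed(self, small_params, small_traj):
        spec = PhantomSpec(
            chamber_half_length=28.0, chamber_radius=11.0, tube_radius=7.0,
            stroke_volume_ml=12.0, e_volume_ml=4.0, a_volume_ml=2.0,
            static_inner_mm=14.0, static_outer_mm=38.0,
            noise_rel_sd=0.02, rr_sd_ms=40.0, resp_amplitude_mm=2.0,
        )
        f = make_phantom(spec)
        rr = sample_rr_intervals(900.0, 40.0, 400, seed=5)
        a = simulate_acquisition(f, small_traj, small_params, rr, seed=9,
                                 resp=RespiratoryTrace(2.0, 3777.0))
        b = simulate_acquisition(f, small_traj, small_params, rr, seed=9,
                                 resp=RespiratoryTrace(2.0, 3777.0))
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.n_beats_total == b.n_beats_total

    def test_completeness(self, small_spec, small_params, small_traj):
        ss = _simulate_small(small_spec, small_params, small_traj)
        assert ss.completeness()


class TestNavigator:
    def test_zero_position_always_accepted(self):
        nav = NavigatorConfig()
        assert navigator_accept(0.0, 0, nav, 8)
        assert navigator_accept(0.0, 7, nav, 8)

    def test_window_is_full_width(self):
        nav = NavigatorConfig(inner_window=4.0, outer_window=7.0)
        # central encode: 2.5 mm > 4/2 -> rejected
        n = 8
        central = n // 2
        assert not navigator_accept(2.5, central, nav, n)
        assert navigator_accept(1.9, central, nav, n)
        # peripheral encode: 7 mm window accepts 2.5 mm
        assert navigator_accept(2.5, 0, nav, n)
        assert not navigator_accept(3.6, 0, nav, n)

    def test_acceptance_fraction_matches_arcsine_oracle(self):
        """Sinusoid 10 mm peak-to-peak vs the closed-form time-in-band fraction."""
        amp = 5.0
        trace = RespiratoryTrace(amp, period_ms=1000.0)
        t = (np.arange(200_000) + 0.5) * (1000.0 / 200_000)
        pos = trace.position(t)
        nav = NavigatorConfig(inner_window=4.0, outer_window=7.0)
        for window in (4.0, 7.0):
            frac = np.mean(np.abs(pos) <= window / 2)
            oracle = (2 / np.pi) * np.arcsin(window / 2 / amp)
            assert frac == pytest.approx(oracle, abs=0.02)

    def test_efficiency_floor_error(self, small_spec, small_params, small_traj):
        field = make_phantom(small_spec)
        rr = sample_rr_intervals(900.0, 0.0, 2000, seed=1)
        with pytest.raises(AcquisitionError):
            simulate_acquisition(
                field, small_traj, small_params, rr, seed=0,
                nav=NavigatorConfig(inner_window=0.2, outer_window=0.2),
                resp=RespiratoryTrace(20.0, 3777.0, phase=0.7),
            )


class TestScanTime:
    def test_no_motion_actual_equals_nominal(self, small_spec, small_params, small_traj):
        ss = _simulate_small(small_spec, small_params, small_traj)
        beats, ratio = actual_scan_time(ss)
        assert ss.n_beats_rejected == 0
        assert ratio == pytest.approx(1.0)

    def test_fifty_percent_efficiency_doubles_scan(self, small_spec, small_params,
                                                   small_traj):
        field = make_phantom(small_spec)
        rr = sample_rr_intervals(900.0, 0.0, 2000, seed=1)
        # square-wave-like trace: inside the window half of the time
        amp = 3.999  # inner window 4 -> |pos| <= 2 for half the sinusoid period
        ss = simulate_acquisition(
            field, small_traj, small_params, rr, seed=0,
            nav=NavigatorConfig(inner_window=4.0, outer_window=4.0),
            resp=RespiratoryTrace(amp, period_ms=7919.0),
        )
        beats, ratio = actual_scan_time(ss)
        # time-in-window fraction of a sinusoid at amp ~ 4/2 / 4: arcsine law
        eff = (2 / np.pi) * np.arcsin(2.0 / amp)
        assert ratio == pytest.approx(1.0 / eff, rel=0.10)
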