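"""Pathline tracing (RK4 + quadrilinear interpolation) and flow components."""

import numpy as np
import pytest

from flow4d import (
    ChamberSegmentations,
    FlowComponents,
    PhantomSpec,
    VelocityVolumeSeries,
    VolumeGrid,
    classify_pathlines,
    conservation_check,
    make_phantom,
    rk4_step,
    seed_positions,
    trace_pathlines,
)
from flow4d.pathlines import VelocitySampler
from flow4d.pipeline import (
    ground_truth_series,
    pathline_flow_analysis,
    phantom_chamber_segmentations,
)


def _series_from_velocity(vel_fn, grid, n_frames=2, frame_dur=450.0):
    """Build a series by evaluating vel_fn(points) (steady field)."""
    pts = grid.points()
    v = vel_fn(pts)  # (N, 3)
    vol = v.T.reshape((3,) + grid.shape)
    vel = np.broadcast_to(vol, (n_frames, 3) + grid.shape).copy()
    mag = np.ones((n_frames,) + grid.shape)
    return VelocityVolumeSeries(mag, vel, grid.voxel_size, frame_dur, 120.0)


@pytest.fixture
def cube_grid():
    return VolumeGrid((40, 40, 40), (2.0, 2.0, 2.0))


class TestRK4:
    def test_uniform_field_is_exact(self, cube_grid):
        v = np.array([0.11, -0.07, 0.05])
        series = _series_from_velocity(
            lambda p: np.broadcast_to(v, p.shape).copy(), cube_grid
        )
        sampler = VelocitySampler(series)
        pos = np.array([[3.0, -5.0, 2.0], [0.0, 0.0, 0.0]])
        new, ok = rk4_step(sampler, pos, 100.0, 5.0)
        np.testing.assert_allclose(new, pos + v * 5.0, atol=1e-12)
        assert ok.all()

    def test_circular_orbit_closure(self, cube_grid):
        """Rigid rotation: a full revolution returns to the start within 0.1%
        of the radius (trilinear interpolation is exact for a linear field)."""
        omega = 2 * np.pi / 360.0  # rad/ms -> one revolution per 360 ms
        series = _series_from_velocity(
            lambda p: np.stack(
                [-omega * p[:, 1], omega * p[:, 0], np.zeros(len(p))], axis=1
            ),
            cube_grid,
        )
        sampler = VelocitySampler(series)
        radius = 15.0
        pos = np.array([[radius, 0.0, 0.0]])
        dt = 5.0
        for _ in range(72):
            pos, ok = rk4_step(sampler, pos, 0.0, dt)
            assert ok.all()
            drift = abs(np.hypot(pos[0, 0], pos[0, 1]) - radius)
            assert drift < (omega * dt) ** 5 * radius + 1e-9
        assert np.linalg.norm(pos[0] - [radius, 0.0, 0.0]) < 1e-3 * radius

    def test_forward_backward_reversibility(self, cube_grid):
        omega = 2 * np.pi / 500.0
        series = _series_from_velocity(
            lambda p: np.stack(
                [-omega * p[:, 1], omega * p[:, 0], np.zeros(len(p))], axis=1
            ),
            cube_grid,
        )
        sampler = VelocitySampler(series)
        pos0 = np.array([[10.0, 5.0, -3.0]])
        pos1, _ = rk4_step(sampler, pos0, 0.0, 5.0)
        pos2, _ = rk4_step(sampler, pos1, 5.0, -5.0)
        assert np.linalg.norm(pos2 - pos0) < 1e-6

    def test_out_of_volume_returns_flag(self, cube_grid):
        series = _series_from_velocity(
            lambda p: np.broadcast_to([1.0, 0, 0], p.shape).copy(), cube_grid
        )
        sampler = VelocitySampler(series)
        new, ok = rk4_step(sampler, np.array([[500.0, 0.0, 0.0]]), 0.0, 5.0)
        assert not ok.any()
        np.testing.assert_array_equal(new, [[500.0, 0.0, 0.0]])


class TestTracing:
    def test_zero_field_stays_put(self, cube_grid):
        series = _series_from_velocity(lambda p: np.zeros_like(p), cube_grid)
        mask = np.zeros(cube_grid.shape, bool)
        mask[15:25, 15:25, 15:25] = True
        inlet = np.zeros_like(mask); inlet[15, 15:25, 15:25] = True
        outlet = np.zeros_like(mask); outlet[24, 15:25, 15:25] = True
        segs = ChamberSegmentations(mask, 0, mask, 1, inlet, outlet)
        seeds, carried = seed_positions(mask, cube_grid)
        res = trace_pathlines(series, seeds, 0.0, 400.0, segs, carried)
        assert not res.exited.any()
        np.testing.assert_allclose(res.final_positions, seeds, atol=1e-12)

    def test_step_halving_convergence_on_phantom(self):
        field = make_phantom(PhantomSpec())
        grid = VolumeGrid((64, 64, 8), (2.8, 2.8, 4.0))
        series = ground_truth_series(field, grid, 20)
        segs = phantom_chamber_segmentations(field, grid, 20)
        seeds, carried = seed_positions(segs.ed_mask, grid)
        rng = np.random.default_rng(0)
        seeds = seeds[rng.choice(len(seeds), 150, replace=False)]
        a = trace_pathlines(series, seeds, 0.0, 320.0, segs, carried, dt=5.0)
        b = trace_pathlines(series, seeds, 0.0, 320.0, segs, carried, dt=2.5)
        # compare particles that stayed in the volume in both runs
        keep = ~a.exited & ~b.exited
        d = np.linalg.norm(a.final_positions[keep] - b.final_positions[keep], axis=1)
        assert d.max() < 0.1 * min(grid.voxel_size)

    def test_systolic_exits_labeled_outlet(self):
        field = make_phantom(PhantomSpec())
        grid = VolumeGrid((64, 64, 8), (2.8, 2.8, 4.0))
        series = ground_truth_series(field, grid, 20)
        segs = phantom_chamber_segmentations(field, grid, 20)
        seeds, carried = seed_positions(segs.ed_mask, grid)
        res = trace_pathlines(series, seeds, 0.0, 320.0, segs, carried)
        exits = res.exit_region[res.exited]
        assert len(exits) > 50
        from flow4d.pathlines import OUTLET
        assert np.mean(exits == OUTLET) >= 0.95


class TestClassification:
    def test_reference_component_additivity(self):
        """Additivity identities on reference patient decompositions."""
        p1 = FlowComponents(direct=17, retained_inflow=39, delayed_ejection=40,
                            residual=87, discarded=0, total_seeded=183)
        assert p1.inflow == 56 and p1.outflow == 57
        p3 = FlowComponents(direct=66, retained_inflow=48, delayed_ejection=46,
                            residual=75, discarded=0, total_seeded=235)
        inflow, outflow, diff = conservation_check(p3)
        assert (inflow, outflow, diff) == (114, 112, 2)

    def test_closed_static_chamber_all_residual(self, cube_grid):
        series = _series_from_velocity(lambda p: np.zeros_like(p), cube_grid)
        mask = np.zeros(cube_grid.shape, bool)
        mask[15:25, 15:25, 15:25] = True
        inlet = np.zeros_like(mask); inlet[15, 18:22, 18:22] = True
        outlet = np.zeros_like(mask); outlet[24, 18:22, 18:22] = True
        segs = ChamberSegmentations(mask, 0, mask, 1, inlet, outlet)
        seeds, carried = seed_positions(mask, cube_grid)
        fwd = trace_pathlines(series, seeds, 0.0, 400.0, segs, carried)
        bwd = trace_pathlines(series, seeds, 0.0, -500.0, segs, carried)
        comps = classify_pathlines(fwd, bwd, segs)
        assert comps.inflow == 0.0 and comps.outflow == 0.0
        assert comps.residual == pytest.approx(comps.total_seeded)

    def test_volume_bookkeeping_closes_exactly(self):
        field = make_phantom(PhantomSpec())
        grid = VolumeGrid((64, 64, 8), (2.8, 2.8, 4.0))
        series = ground_truth_series(field, grid, 20)
        segs = phantom_chamber_segmentations(field, grid, 20)
        comps = pathline_flow_analysis(series, segs, 320.0)
        total = (comps.direct + comps.retained_inflow + comps.delayed_ejection
                 + comps.residual + comps.discarded)
        assert total == pytest.approx(comps.total_seeded, abs=1e-9)

    def test_phantom_components_match_flux_bookkeeping_oracle(self):
        """Pathline component volumes vs Eulerian flux integration: the
        diastolic inlet volume is the inflow, the systolic outlet volume the
        outflow (all filling passes the inlet; all ejection the outlet)."""
        spec = PhantomSpec()
        field = make_phantom(spec)
        grid = VolumeGrid((64, 64, 8), (2.8, 2.8, 4.0))
        series = ground_truth_series(field, grid, 20)
        segs = phantom_chamber_segmentations(field, grid, 20)
        comps = pathline_flow_analysis(series, segs, spec.systolic_duration_ms)
        ts = np.linspace(0, 900, 9000, endpoint=False)
        q = field.flux(ts)
        dia = q[ts >= spec.systolic_duration_ms].sum() * 0.1 / 1000.0
        sys_ = q[ts < spec.systolic_duration_ms].sum() * 0.1 / 1000.0
        assert comps.inflow == pytest.approx(dia, rel=0.05)
        assert comps.outflow == pytest.approx(sys_, rel=0.05)

    def test_mismatched_seeds_raise(self, cube_grid):
        series = _series_from_velocity(lambda p: np.zeros_like(p), cube_grid)
        mask = np.zeros(cube_grid.shape, bool); mask[18:22, 18:22, 18:22] = True
        segs = ChamberSegmentations(mask, 0, mask, 1, mask & False, mask & False)
        seeds, carried = seed_positions(mask, cube_grid)
        fwd = trace_pathlines(series, seeds, 0.0, 100.0, segs, carried)
        bwd = trace_pathlines(series, seeds[:-2], 0.0, -100.0, segs, carried)
        with pytest.raises(ValueError):
            classify_pathlines(fwd, bwd, segs)
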