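"""Pathline tracing and four-component decomposition of chamber flow.

Massless particles are advected through the time-resolved velocity field
with a classical four-stage Runge-Kutta scheme, quadrilinear (x, y, z, t)
interpolation and a 5 ms step; the field is periodic in the cardiac cycle.
Pathlines are released from every voxel of the chamber segmentation at end
diastole and traced forward through systole and backward through diastole.
The chamber segmentation at end systole decides if and where a pathline
left (or entered) the chamber; each crossing is attributed to the nearest
labeled surface element (inlet, outlet, or wall).  The flow components are:

- direct flow: entered during diastole and left during systole;
- retained inflow: entered, did not leave;
- delayed ejection: did not enter, left;
- residual volume: neither entered nor left.

Pathlines crossing the wall (myocardium) are discarded.  Inflow = direct +
retained; outflow = direct + delayed; mass conservation demands that the
two agree, which makes this decomposition a sensitive end-to-end quality
check of the velocity data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .recon import VelocityVolumeSeries

__all__ = [
    "ChamberSegmentations",
    "Pathline",
    "PathlineSet",
    "FlowComponents",
    "VelocitySampler",
    "rk4_step",
    "trace_pathlines",
    "classify_pathlines",
    "conservation_check",
    "seed_positions",
]

DEFAULT_STEP_MS = 5.0

WALL, INLET, OUTLET = 0, 1, 2


@dataclass
class ChamberSegmentations:
    """Chamber masks at end diastole / end systole with labeled boundary.

    ``inlet_region`` and ``outlet_region`` are boolean volumes marking the
    inlet/outlet portions of the end-systolic surface; every other surface
    element is wall (myocardium).
    """

    ed_mask: np.ndarray
    ed_frame: int
    es_mask: np.ndarray
    es_frame: int
    inlet_region: np.ndarray
    outlet_region: np.ndarray

    def __post_init__(self) -> None:
        self.ed_mask = np.asarray(self.ed_mask, bool)
        self.es_mask = np.asarray(self.es_mask, bool)
        self.inlet_region = np.asarray(self.inlet_region, bool)
        self.outlet_region = np.asarray(self.outlet_region, bool)
        if not self.ed_mask.any() or not self.es_mask.any():
            raise ValueError("chamber masks must be non-empty")
        if self.ed_frame == self.es_frame:
            raise ValueError("end-diastolic and end-systolic frames must differ")


class VelocitySampler:
    """Quadrilinear (x, y, z, t) interpolator of a velocity volume series.

    Time is periodic over the cycle; spatial queries outside the volume
    return zero velocity and raise the out-of-volume flag that terminates a
    trajectory.  Positions in mm (half-open voxel convention), velocities in
    m/s == mm/ms.
    """

    def __init__(self, series: VelocityVolumeSeries):
        self.series = series
        self.grid = series.grid
        self.cycle_ms = series.n_frames * series.frame_duration
        nx, ny, nz = self.grid.shape
        # pad one voxel so edge interpolation falls to zero smoothly
        self._v = np.zeros((series.n_frames, 3, nx + 2, ny + 2, nz + 2))
        self._v[:, :, 1:-1, 1:-1, 1:-1] = series.velocity
        self._origin = np.array(
            [self.grid.axis_coords(a)[0] for a in range(3)]
        )  # coordinate of voxel center (0,0,0)
        self._delta = np.asarray(self.grid.voxel_size, dtype=float)

    def _frame_weights(self, t: float) -> tuple[int, int, float]:
        """Frames bracketing time t (frame f holds the bin center time)."""
        ft = (t / self.series.frame_duration - 0.5) % self.series.n_frames
        f0 = int(np.floor(ft)) % self.series.n_frames
        f1 = (f0 + 1) % self.series.n_frames
        return f0, f1, ft - np.floor(ft)

    def sample(self, pos: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Velocities (N, 3) at positions (N, 3) and time t; also inside flags."""
        pos = np.atleast_2d(pos)
        f0, f1, wt = self._frame_weights(t)
        # continuous index into the padded array
        u = (pos - self._origin) / self._delta + 1.0
        nx, ny, nz = self.grid.shape
        inside = np.all((u >= 0.0) & (u <= np.array([nx + 1, ny + 1, nz + 1])), axis=1)
        uc = np.clip(u, 0.0, np.array([nx, ny, nz], float) + 1.0 - 1e-9)
        i0 = np.floor(uc).astype(int)
        frac = uc - i0
        out = np.zeros((pos.shape[0], 3))
        for vol, w in ((self._v[f0], 1.0 - wt), (self._v[f1], wt)):
            if w == 0.0:
                continue
            acc = np.zeros_like(out)
            for dx in (0, 1):
                wx = (1 - frac[:, 0]) if dx == 0 else frac[:, 0]
                for dy in (0, 1):
                    wy = (1 - frac[:, 1]) if dy == 0 else frac[:, 1]
                    for dz in (0, 1):
                        wz = (1 - frac[:, 2]) if dz == 0 else frac[:, 2]
                        wgt = wx * wy * wz
                        acc += wgt[:, None] * vol[
                            :, i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                        ].T
            out += w * acc
        out[~inside] = 0.0
        return out, inside


def rk4_step(
    sampler: VelocitySampler, pos: np.ndarray, t: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """One classical RK4 step; ``dt`` may be negative for backward tracing.

    Returns the new positions and the inside-volume flags (a position that
    samples outside the volume sees zero velocity and is flagged; callers
    terminate such trajectories rather than raising).
    """
    k1, in1 = sampler.sample(pos, t)
    k2, in2 = sampler.sample(pos + 0.5 * dt * k1, t + 0.5 * dt)
    k3, in3 = sampler.sample(pos + 0.5 * dt * k2, t + 0.5 * dt)
    k4, in4 = sampler.sample(pos + dt * k3, t + dt)
    new = pos + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return new, in1 & in2 & in3 & in4


@dataclass
class Pathline:
    """One traced trajectory with its carried volume and crossing record."""

    seed: np.ndarray
    carried_volume: float  # ml
    times: np.ndarray
    positions: np.ndarray
    crossing_time: float | None
    crossing_region: int | None  # WALL / INLET / OUTLET
    status: str  # "kept" or "discarded"


@dataclass
class PathlineSet:
    """Batch result of tracing all seeds in one direction."""

    seeds: np.ndarray  # (N, 3)
    carried_volume: float  # ml per pathline
    exited: np.ndarray  # (N,) bool: crossed the chamber surface
    exit_region: np.ndarray  # (N,) int label of the first crossing
    exit_time: np.ndarray  # (N,) ms (nan if no crossing)
    final_positions: np.ndarray
    trajectories: np.ndarray | None = None  # (n_steps+1, N, 3) if kept


@dataclass
class FlowComponents:
    """Four-component decomposition of the chamber volume (ml)."""

    direct: float
    retained_inflow: float
    delayed_ejection: float
    residual: float
    discarded: float
    total_seeded: float

    @property
    def inflow(self) -> float:
        return self.direct + self.retained_inflow

    @property
    def outflow(self) -> float:
        return self.direct + self.delayed_ejection

    @property
    def discarded_fraction(self) -> float:
        return self.discarded / self.total_seeded if self.total_seeded else 0.0


def seed_positions(
    mask: np.ndarray, grid, seeds_per_voxel_axis: int = 1
) -> tuple[np.ndarray, float]:
    """Seed coordinates inside a mask and the volume each seed carries (ml).

    One seed per voxel center by default; ``seeds_per_voxel_axis = k``
    subdivides each voxel into k^3 seeds.
    """
    k = int(seeds_per_voxel_axis)
    if k < 1:
        raise ValueError("seeds_per_voxel_axis must be >= 1")
    idx = np.argwhere(np.asarray(mask, bool))
    delta = np.asarray(grid.voxel_size, dtype=float)
    lows = idx * delta + np.array([grid.axis_coords(a)[0] for a in range(3)]) - delta / 2
    offs = (np.arange(k) + 0.5) / k
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    pos = (lows[:, None, :] + sub[None, :, :] * delta).reshape(-1, 3)
    carried = grid.voxel_volume / (k**3) / 1000.0  # mm^3 -> ml
    return pos, carried


class _SurfaceLabeler:
    """Nearest labeled boundary voxel of the end-systolic surface."""

    def __init__(self, segs: ChamberSegmentations, grid):
        es = segs.es_mask
        interior = np.ones_like(es)
        sl = np.s_[1:-1]
        interior[sl, sl, sl] = (
            es[2:, 1:-1, 1:-1] & es[:-2, 1:-1, 1:-1]
            & es[1:-1, 2:, 1:-1] & es[1:-1, :-2, 1:-1]
            & es[1:-1, 1:-1, 2:] & es[1:-1, 1:-1, :-2]
        )
        boundary = es & ~(es & interior)
        idx = np.argwhere(boundary)
        delta = np.asarray(grid.voxel_size, dtype=float)
        origin = np.array([grid.axis_coords(a)[0] for a in range(3)])
        pts = idx * delta + origin
        labels = np.zeros(idx.shape[0], dtype=int)
        labels[segs.inlet_region[tuple(idx.T)]] = INLET
        labels[segs.outlet_region[tuple(idx.T)]] = OUTLET
        self._tree = cKDTree(pts)
        self._labels = labels

    def label(self, points: np.ndarray) -> np.ndarray:
        _, i = self._tree.query(np.atleast_2d(points))
        return self._labels[i]


def _mask_interp(mask: np.ndarray, grid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a mask (smooths voxel jaggedness)."""
    m = np.zeros(tuple(n + 2 for n in mask.shape))
    m[1:-1, 1:-1, 1:-1] = mask
    delta = np.asarray(grid.voxel_size, dtype=float)
    origin = np.array([grid.axis_coords(a)[0] for a in range(3)])
    u = (np.atleast_2d(points) - origin) / delta + 1.0
    u = np.clip(u, 0.0, np.array(mask.shape, float) + 1.0 - 1e-9)
    i0 = np.floor(u).astype(int)
    f = u - i0
    out = np.zeros(u.shape[0])
    for dx in (0, 1):
        wx = (1 - f[:, 0]) if dx == 0 else f[:, 0]
        for dy in (0, 1):
            wy = (1 - f[:, 1]) if dy == 0 else f[:, 1]
            for dz in (0, 1):
                wz = (1 - f[:, 2]) if dz == 0 else f[:, 2]
                out += wx * wy * wz * m[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def trace_pathlines(
    series: VelocityVolumeSeries,
    seeds: np.ndarray,
    t0: float,
    t1: float,
    segs: ChamberSegmentations,
    carried_volume: float,
    dt: float = DEFAULT_STEP_MS,
    keep_trajectories: bool = False,
) -> PathlineSet:
    """Integrate all seeds from ``t0`` to ``t1`` and record surface crossings.

    The sign of the step follows the direction (``t1 < t0`` traces
    backward); cycle time wraps periodically.  A pathline's first crossing
    of the end-systolic chamber surface is attributed to the nearest labeled
    surface element; leaving the image volume terminates a trajectory
    (recorded by flag, not an exception).
    """
    sampler = VelocitySampler(series)
    labeler = _SurfaceLabeler(segs, series.grid)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = seeds.shape[0]
    step = abs(dt) * (1.0 if t1 >= t0 else -1.0)
    n_steps = int(np.ceil(abs(t1 - t0) / abs(dt) - 1e-9))

    pos = seeds.copy()
    alive = np.ones(n, dtype=bool)  # still integrating (inside image)
    inside_ch = _mask_interp(segs.es_mask, series.grid, pos) >= 0.5
    exited = np.zeros(n, dtype=bool)
    exit_region = np.full(n, -1, dtype=int)
    exit_time = np.full(n, np.nan)
    traj = [pos.copy()] if keep_trajectories else None

    t = float(t0)
    for i in range(n_steps):
        h = step
        if (step > 0 and t + h > t1) or (step < 0 and t + h < t1):
            h = t1 - t
        new = pos.copy()
        if alive.any():
            stepped, ok = rk4_step(sampler, pos[alive], t, h)
            new[alive] = stepped
            still = alive.copy()
            still[alive] = ok
        else:
            still = alive
        t += h
        now_inside = _mask_interp(segs.es_mask, series.grid, new) >= 0.5
        crossed = alive & inside_ch & ~now_inside & ~exited
        if crossed.any():
            exited[crossed] = True
            exit_region[crossed] = labeler.label(new[crossed])
            exit_time[crossed] = t
        inside_ch = now_inside
        pos = new
        alive = still
        if traj is not None:
            traj.append(pos.copy())

    return PathlineSet(
        seeds=seeds,
        carried_volume=carried_volume,
        exited=exited,
        exit_region=exit_region,
        exit_time=exit_time,
        final_positions=pos,
        trajectories=np.array(traj) if traj is not None else None,
    )


def classify_pathlines(
    fwd: PathlineSet, bwd: PathlineSet, segs: ChamberSegmentations
) -> FlowComponents:
    """Combine forward and backward traces into the four flow components.

    ``fwd`` is traced end diastole -> end systole (through systole), ``bwd``
    end diastole -> previous end systole (through diastole, backward in
    time).  A pathline *entered* iff its backward trace leaves the chamber
    through the inlet region; it *left* iff its forward trace leaves through
    the outlet region.  Any wall-region crossing discards the pathline.
    Volumes close exactly: direct + retained + delayed + residual +
    discarded = seeded volume.
    """
    if fwd.seeds.shape != bwd.seeds.shape:
        raise ValueError("forward and backward sets must share their seeds")
    vol = fwd.carried_volume
    wall = (fwd.exited & (fwd.exit_region == WALL)) | (
        bwd.exited & (bwd.exit_region == WALL)
    )
    entered = bwd.exited & (bwd.exit_region == INLET) & ~wall
    left = fwd.exited & (fwd.exit_region == OUTLET) & ~wall
    n = fwd.seeds.shape[0]
    n_wall = int(wall.sum())
    keep = ~wall
    direct = int((entered & left)[keep].sum())
    retained = int((entered & ~left)[keep].sum())
    delayed = int((~entered & left)[keep].sum())
    residual = int((~entered & ~left)[keep].sum())
    return FlowComponents(
        direct=direct * vol,
        retained_inflow=retained * vol,
        delayed_ejection=delayed * vol,
        residual=residual * vol,
        discarded=n_wall * vol,
        total_seeded=n * vol,
    )


def conservation_check(components: FlowComponents) -> tuple[float, float, float]:
    """(inflow, outflow, inflow - outflow) in ml."""
    return (
        components.inflow,
        components.outflow,
        components.inflow - components.outflow,
    )
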