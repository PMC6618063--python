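"""Velocity-encoded k-space acquisition simulator with navigator gating.

Simulates a retrospectively gated four-point phase-contrast acquisition of
the analytic phantom: one k-space line group per cardiac cycle, heart-phase
slots advancing every ``segmentation_factor * 4 * TR``, and within each slot
the reference plus three velocity-encoded segments acquired in succession.
A respiratory navigator accepts or rejects whole beats; rejected lines are
re-queued (immediately re-acquired in the next beat) until the k-space is
complete.

Signal model: the object is the phantom sampled at the voxel centers of the
encoded grid, frozen at each readout's center time; the recorded samples are
the non-uniform discrete Fourier transform of ``m(r) * exp(i phi(r))`` at
the trajectory coordinates, with ``phi = pi * v_d / venc`` for encoded
segment ``d`` (zero for the reference), plus complex white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import AnalyticFlowField, VolumeGrid
from .sequence import SequenceParams, SpiralTrajectory, n_encoded_slices

__all__ = [
    "NavigatorConfig",
    "RespiratoryTrace",
    "ReadoutEvent",
    "KSpaceSampleSet",
    "AcquisitionError",
    "navigator_accept",
    "central_slice_encodes",
    "simulate_acquisition",
    "actual_scan_time",
    "object_snapshot",
    "nudft_samples",
    "acquisition_grid",
    "SEGMENT_NAMES",
]

SEGMENT_NAMES = ("ref", "vx", "vy", "vz")


class AcquisitionError(RuntimeError):
    """Raised when the simulated acquisition cannot complete."""


@dataclass(frozen=True)
class NavigatorConfig:
    """Respiratory navigator acceptance windows (full widths, mm).

    The tight window applies to the central fraction of slice encodes
    (ranked by |kz|); the loose window to the periphery.  Defaults: 4 mm
    inner window over the central 25%, 7 mm outside.
    """

    inner_window: float = 4.0
    outer_window: float = 7.0
    central_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.inner_window > self.outer_window:
            raise ValueError("inner window must not exceed outer window")
        if not 0.0 < self.central_fraction <= 1.0:
            raise ValueError("central_fraction must be in (0, 1]")


@dataclass(frozen=True)
class RespiratoryTrace:
    """Sinusoidal diaphragm position model, mm (peak amplitude, not p-p)."""

    amplitude_mm: float = 3.0
    period_ms: float = 4000.0
    phase: float = 0.0

    def position(self, t_ms) -> np.ndarray:
        return self.amplitude_mm * np.sin(
            2.0 * np.pi * np.asarray(t_ms, dtype=float) / self.period_ms + self.phase
        )


@dataclass
class ReadoutEvent:
    """One velocity-encoding segment of one k-space line."""

    line: int  # in-plane line index (interleaf)
    slice_encode: int  # kz partition index
    segment: int  # 0=ref, 1=vx, 2=vy, 3=vz
    t_abs: float  # ms from scan start (readout center)
    t_since_r: float  # ms from the R wave of the containing beat
    rr: float  # ms, length of the containing beat
    nav_position: float  # mm
    accepted: bool


def central_slice_encodes(n_encodes: int, fraction: float) -> np.ndarray:
    """Boolean mask of encodes in the central ``fraction`` by |kz| rank."""
    centers = np.abs(np.arange(n_encodes) - n_encodes // 2)
    order = np.argsort(centers, kind="stable")
    n_central = max(1, int(np.ceil(fraction * n_encodes)))
    mask = np.zeros(n_encodes, dtype=bool)
    mask[order[:n_central]] = True
    return mask


def navigator_accept(
    position: float, slice_encode: int, nav: NavigatorConfig, n_slice_encodes: int
) -> bool:
    """Accept a readout if the navigator sits inside the acceptance window.

    The window is the full width: a position is accepted iff
    ``|position| <= window / 2``, with the inner window for the central
    fraction of slice encodes and the outer window elsewhere.
    """
    central = central_slice_encodes(n_slice_encodes, nav.central_fraction)
    window = nav.inner_window if central[slice_encode] else nav.outer_window
    return abs(position) <= window / 2.0


def acquisition_grid(params: SequenceParams) -> VolumeGrid:
    """Encoded image grid of the acquisition (slice oversampling included)."""
    n_enc = n_encoded_slices(params)
    return VolumeGrid(
        shape=(params.matrix[0], params.matrix[1], n_enc),
        voxel_size=(params.voxel_size, params.voxel_size, params.slice_thickness),
    )


def object_snapshot(
    field: AnalyticFlowField,
    grid: VolumeGrid,
    t: float,
    rr: float,
    segment: int,
    venc: float,
) -> np.ndarray:
    """Complex object ``m(r) exp(i pi v_d / venc)`` frozen at time ``t``.

    Reference implementation of the signal model (used directly by the
    brute-force oracles; the fast simulator path reproduces it exactly by
    splitting static and fluid contributions).  ``venc`` in cm/s.
    """
    pts = grid.points()
    mag = field.magnitude(pts)
    if segment == 0:
        img = mag.astype(complex)
    else:
        v = field.velocity(pts, t, rr)[:, segment - 1]  # m/s
        img = mag * np.exp(1j * np.pi * v / (venc / 100.0))
    return img.reshape(grid.shape)


def nudft_samples(
    image: np.ndarray, grid: VolumeGrid, kx: np.ndarray, ky: np.ndarray, kz: float
) -> np.ndarray:
    """Direct (brute-force) non-uniform DFT of a gridded object."""
    xs, ys, zs = grid.meshgrid()
    img = image.ravel()
    x, y, z = xs.ravel(), ys.ravel(), zs.ravel()
    phase = np.exp(
        -2j * np.pi * (np.outer(kx, x) + np.outer(ky, y) + kz * z[None, :])
    )
    return phase @ img


@dataclass
class KSpaceSampleSet:
    """Complete accepted acquisition: events plus complex sample arrays."""

    events: list[ReadoutEvent]
    samples: np.ndarray  # (n_events, n_samples) complex
    trajectory: SpiralTrajectory
    params: SequenceParams
    noise_sd: float
    seed: int
    n_beats_total: int
    n_beats_rejected: int
    rr_mean_accepted: float

    @property
    def n_events(self) -> int:
        return len(self.events)

    def completeness(self) -> bool:
        """Every (line, slice-encode, segment) has at least one acquisition."""
        seen = np.zeros(
            (self.trajectory.n_lines, self.trajectory.n_slice_encodes, 4), dtype=bool
        )
        for ev in self.events:
            seen[ev.line, ev.slice_encode, ev.segment] = True
        return bool(seen.all())


def _fluid_layout(field: AnalyticFlowField, grid: VolumeGrid):
    """Index bookkeeping for the fluid voxels: xy footprint and z membership."""
    pts = grid.points()
    fluid = field.fluid_mask(pts).reshape(grid.shape)
    nx, ny, nz = grid.shape
    xy_foot = fluid.any(axis=2)  # (nx, ny)
    xy_idx = np.flatnonzero(xy_foot.ravel())
    xy_pos = -np.ones(nx * ny, dtype=int)
    xy_pos[xy_idx] = np.arange(xy_idx.size)
    vox = np.argwhere(fluid)  # (n_fluid, 3)
    vox_xy = xy_pos[vox[:, 0] * ny + vox[:, 1]]
    return fluid, xy_idx, vox, vox_xy


def simulate_acquisition(
    field: AnalyticFlowField,
    traj: SpiralTrajectory,
    params: SequenceParams,
    rr_seq: np.ndarray,
    nav: NavigatorConfig | None = None,
    resp: RespiratoryTrace | None = None,
    seed: int = 0,
    noise_rel: float | None = None,
    efficiency_floor: float = 0.05,
) -> KSpaceSampleSet:
    """Simulate the full retrospectively gated acquisition.

    ``rr_seq`` supplies one RR interval per heartbeat consumed (accepted or
    rejected); it must be long enough to absorb the navigator rejections.
    ``noise_rel`` is the complex noise SD relative to the fluid magnitude in
    image units (defaults to the phantom spec value); it is converted to a
    per-sample k-space SD via the unitary-DFT scaling ``sqrt(n_voxels)``.

    Raises
    ------
    AcquisitionError
        If the acceptance efficiency falls below ``efficiency_floor`` (the
        RR sequence is exhausted before k-space is complete).
    """
    nav = nav or NavigatorConfig()
    resp = resp if resp is not None else RespiratoryTrace(0.0)
    rr_seq = np.asarray(rr_seq, dtype=float)
    grid = acquisition_grid(params)
    if grid.shape[2] != traj.n_slice_encodes:
        raise ValueError("trajectory slice encodes do not match params")
    if abs(grid.voxel_size[0] - 1.0 / (2 * traj.kmax)) > 1e-6:
        raise ValueError("trajectory kmax does not match params voxel size")
    venc_ms = params.venc / 100.0  # m/s

    spec = field.spec
    sigma_img = spec.noise_rel_sd if noise_rel is None else noise_rel
    sigma_k = sigma_img * spec.magnitude_fluid * np.sqrt(np.prod(grid.shape))

    # --- static (zero-velocity) part, cached per (line, kz encode) --------
    pts = grid.points()
    mag = field.magnitude(pts).reshape(grid.shape)
    fluid, xy_idx, vox, vox_xy = _fluid_layout(field, grid)
    static_img = np.where(fluid, 0.0, mag)
    nx, ny, nz = grid.shape
    xc, yc = grid.axis_coords(0), grid.axis_coords(1)
    zc = grid.axis_coords(2)
    kz_vals = traj.kz
    zphase = np.exp(-2j * np.pi * np.outer(kz_vals, zc))  # (n_kz, nz)

    n_lines = traj.n_lines
    n_kz = traj.n_slice_encodes
    n_samp = traj.n_samples

    # in-plane exponentials restricted to footprints
    stat_xy = np.flatnonzero(np.abs(static_img).sum(axis=2).ravel())
    sx, sy = np.unravel_index(stat_xy, (nx, ny))
    fx, fy = np.unravel_index(xy_idx, (nx, ny))
    fluid_mag = mag[vox[:, 0], vox[:, 1], vox[:, 2]]
    fluid_pts = np.stack(
        [xc[vox[:, 0]], yc[vox[:, 1]], zc[vox[:, 2]]], axis=1
    )
    vox_zphase = zphase[:, vox[:, 2]]  # (n_kz, n_fluid)

    n_fl_xy = xy_idx.size
    w_stat_all = static_img[sx, sy, :] @ zphase.T  # (n_stat_xy, n_kz)
    w_ref_all = np.zeros((n_fl_xy, n_kz), dtype=complex)
    np.add.at(w_ref_all, vox_xy, fluid_mag[:, None] * vox_zphase.T)

    static_cache = np.empty((n_lines, n_kz, n_samp), dtype=complex)
    ref_fluid_cache = np.empty((n_lines, n_kz, n_samp), dtype=complex)
    e_fluid = []
    for li in range(n_lines):
        kx, ky = traj.line_samples(li)
        e_stat = np.exp(
            -2j * np.pi * (np.outer(kx, xc[sx]) + np.outer(ky, yc[sy]))
        )
        e_fl = np.exp(-2j * np.pi * (np.outer(kx, xc[fx]) + np.outer(ky, yc[fy])))
        e_fluid.append(e_fl)
        static_cache[li] = (e_stat @ w_stat_all).T
        ref_fluid_cache[li] = (e_fl @ w_ref_all).T

    # --- beat loop ---------------------------------------------------------
    seg_f = params.segmentation_factor
    slot_len = seg_f * params.n_flow_segments * params.tr
    kz_order = np.argsort(np.abs(np.arange(n_kz) - n_kz // 2), kind="stable")
    line_queue = [(int(zi), li) for zi in kz_order for li in range(n_lines)]
    groups = [line_queue[i : i + seg_f] for i in range(0, len(line_queue), seg_f)]

    rng = np.random.default_rng(seed)
    events: list[ReadoutEvent] = []
    sample_rows: list[np.ndarray] = []
    t_abs = 0.0
    beats = 0
    rejected = 0
    rr_accepted: list[float] = []
    gi = 0
    prev_group = None  # group still playing out in the slot straddling the R wave

    def record(group, zi, li, t_read, rr, t0_beat, nav_pos):
        row = static_cache[li, zi].copy()
        seg = group[2]
        if seg == 0:
            row += ref_fluid_cache[li, zi]
        else:
            v = field.velocity(fluid_pts, t_read, rr)[:, seg - 1]
            cvals = fluid_mag * np.exp(1j * np.pi * v / venc_ms)
            w = np.zeros(n_fl_xy, dtype=complex)
            np.add.at(w, vox_xy, cvals * vox_zphase[zi])
            row += e_fluid[li] @ w
        if sigma_k > 0:
            noise = rng.normal(0.0, sigma_k, size=(2, n_samp))
            row = row + noise[0] + 1j * noise[1]
        events.append(
            ReadoutEvent(
                line=li,
                slice_encode=zi,
                segment=seg,
                t_abs=t0_beat + t_read,
                t_since_r=t_read,
                rr=rr,
                nav_position=nav_pos,
                accepted=True,
            )
        )
        sample_rows.append(row)

    # The sequence free-runs: heart-phase slots sit on a continuous
    # absolute-time grid, so the slot phase relative to the R wave varies
    # from beat to beat (this is what lets retrospective binning cover the
    # whole normalized cycle, including the frames right at the R wave).
    # The k-space line group switches at the first slot boundary at or
    # after each R wave; the readouts of a slot that straddles the R wave
    # are timestamped within the beat that contains them.
    while gi < len(groups):
        if beats >= rr_seq.size:
            eff = (beats - rejected) / max(beats, 1)
            raise AcquisitionError(
                f"RR sequence exhausted after {beats} beats "
                f"(acceptance efficiency {eff:.2f}, floor {efficiency_floor})"
            )
        rr = float(rr_seq[beats])
        group = groups[gi]
        nav_pos = float(resp.position(t_abs))
        ok = navigator_accept(nav_pos, group[0][0], nav, n_kz)
        beats += 1
        if not ok:
            rejected += 1
            prev_group = None  # rejected beat: its tail is discarded too
            t_abs += rr
            if rejected > efficiency_floor ** -1 * len(groups) + 50:
                raise AcquisitionError(
                    "navigator acceptance efficiency below floor "
                    f"{efficiency_floor}"
                )
            continue
        rr_accepted.append(rr)
        n_recorded = 0
        s_first = int(np.floor(t_abs / slot_len + 1e-9))
        s_last = int(np.floor((t_abs + rr) / slot_len - 1e-9))
        for s in range(s_first, s_last + 1):
            t_slot = s * slot_len  # absolute slot start
            slot_group = group if t_slot >= t_abs - 1e-9 else prev_group
            if slot_group is None:
                continue
            for gpos, (zi, li) in enumerate(slot_group):
                for seg in range(4):
                    t_read = (
                        t_slot
                        - t_abs
                        + gpos * params.n_flow_segments * params.tr
                        + (seg + 0.5) * params.tr
                    )
                    if not 0.0 <= t_read < rr:
                        continue
                    record((zi, li, seg), zi, li, t_read, rr, t_abs, nav_pos)
                    if slot_group is group:
                        n_recorded += 1
        if n_recorded == 0:
            # degenerate short beat: guarantee the pending line is acquired
            for gpos, (zi, li) in enumerate(group):
                for seg in range(4):
                    t_read = min(
                        gpos * params.n_flow_segments * params.tr
                        + (seg + 0.5) * params.tr,
                        rr * (1 - 1e-9),
                    )
                    record((zi, li, seg), zi, li, t_read, rr, t_abs, nav_pos)
        prev_group = group
        t_abs += rr
        gi += 1

    return KSpaceSampleSet(
        events=events,
        samples=np.asarray(sample_rows),
        trajectory=traj,
        params=params,
        noise_sd=sigma_k,
        seed=seed,
        n_beats_total=beats,
        n_beats_rejected=rejected,
        rr_mean_accepted=float(np.mean(rr_accepted)),
    )


def actual_scan_time(sample_set: KSpaceSampleSet) -> tuple[int, float]:
    """Beats consumed (including rejections) and the ratio to nominal."""
    nominal = sample_set.n_beats_total - sample_set.n_beats_rejected
    if sample_set.n_beats_total == 0:
        return 0, 0.0
    return sample_set.n_beats_total, sample_set.n_beats_total / max(nominal, 1)
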