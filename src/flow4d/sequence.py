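"""Stack-of-spirals and Cartesian gradient-echo sequence design.

Designs slew- and amplitude-limited variable-density Archimedean spiral
interleaves for a stack-of-spirals 3D phase-contrast acquisition, plus the
reference Cartesian phase-encode enumeration, and evaluates the sequence
timing quantities (nominal temporal resolution, nominal scan time in cardiac
cycles).

Units: k-space in cycles/mm, gradients in mT/m, slew in T/m/s, times in ms,
distances in mm.  The gyromagnetic ratio enters as gamma-bar expressed in
cycles/mm/ms per mT/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_BAR",
    "GradientLimits",
    "SequenceParams",
    "DensityProfile",
    "SpiralTrajectory",
    "CartesianTrajectory",
    "InfeasibleReadoutError",
    "design_spiral_interleaf",
    "cartesian_trajectory",
    "nominal_temporal_resolution",
    "nominal_scan_time",
    "n_encoded_slices",
]

#: gamma/2pi for protons, converted to cycles/mm/ms per mT/m of gradient.
GAMMA_BAR = 42.577478461e6 * 1e-9  # = 0.042577... (1/mm/ms)/(mT/m)


class InfeasibleReadoutError(ValueError):
    """Raised when kmax cannot be reached within the readout duration."""


@dataclass(frozen=True)
class GradientLimits:
    """Gradient system hardware limits.

    Defaults correspond to a 1.5 T clinical system with 33 mT/m maximum
    gradient amplitude and 180 T/m/s maximum slew rate.
    """

    max_gradient: float = 33.0  # mT/m
    max_slew: float = 180.0  # T/m/s
    raster_time: float = 10.0  # microseconds

    def __post_init__(self) -> None:
        if self.max_gradient <= 0 or self.max_slew <= 0 or self.raster_time <= 0:
            raise ValueError("gradient limits must be strictly positive")

    @property
    def raster_ms(self) -> float:
        return self.raster_time * 1e-3

    @property
    def max_slew_mt_m_ms(self) -> float:
        """Slew expressed in mT/m per ms (numerically equal to T/m/s)."""
        return self.max_slew


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of one 4D flow protocol.

    The defaults reproduce the spiral protocol: TR 12 ms, TE 3.7 ms,
    venc 120 cm/s, 10 interleaves, 5 ms readouts, 280 mm FOV, 100x100
    matrix (2.8 mm isotropic in-plane), 27% slice oversampling and
    four-point velocity encoding (one reference + three encoded segments)
    at segmentation factor 1.
    """

    tr: float = 12.0  # ms
    te: float = 3.7  # ms
    venc: float = 120.0  # cm/s
    n_interleaves: int = 10
    readout_duration: float = 5.0  # ms
    fov: tuple[float, float] = (280.0, 280.0)  # mm
    matrix: tuple[int, int] = (100, 100)
    n_slices_recon: int = 36
    slice_oversampling: float = 0.27
    slice_thickness: float = 2.8  # mm
    flip_angle: float = 8.0  # degrees
    segmentation_factor: int = 1  # k-space lines per heart phase
    n_flow_segments: int = 4  # reference + 3 velocity-encoded

    def __post_init__(self) -> None:
        if self.n_flow_segments != 4:
            raise ValueError("four-point velocity encoding requires 4 flow segments")
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")
        if self.slice_oversampling < 0:
            raise ValueError("slice_oversampling must be >= 0")
        if min(self.fov) <= 0 or min(self.matrix) <= 0:
            raise ValueError("FOV and matrix must be positive")
        vx = self.fov[0] / self.matrix[0]
        vy = self.fov[1] / self.matrix[1]
        if abs(vx - vy) > 1e-9 * vx:
            raise ValueError("in-plane voxel size must be isotropic")
        if self.tr <= 0 or self.venc <= 0 or self.readout_duration <= 0:
            raise ValueError("tr, venc and readout_duration must be positive")
        if self.segmentation_factor < 1:
            raise ValueError("segmentation_factor must be >= 1")

    @property
    def voxel_size(self) -> float:
        """In-plane voxel size in mm."""
        return self.fov[0] / self.matrix[0]

    @property
    def kmax(self) -> float:
        """Nyquist in-plane k-space radius in cycles/mm."""
        return 1.0 / (2.0 * self.voxel_size)


@dataclass(frozen=True)
class DensityProfile:
    """Two-zone variable-density descriptor for the spiral readout.

    The spiral is fully sampled (adjacent-turn radial spacing equal to
    ``n_interleaves / FOV``) out to ``core_fraction * kmax``; beyond the core
    the spacing widens linearly until it reaches ``undersampling * nominal``
    at kmax.  ``undersampling = 1`` is a uniform, fully sampled spiral.
    """

    core_fraction: float = 0.2
    undersampling: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in (0, 1]")
        if self.undersampling < 1.0:
            raise ValueError("undersampling must be >= 1")

    def factor(self, r: float, kmax: float) -> float:
        """Local spacing multiplier at radius ``r``."""
        core = self.core_fraction * kmax
        if r <= core:
            return 1.0
        if kmax <= core:
            return 1.0
        frac = (r - core) / (kmax - core)
        return 1.0 + (self.undersampling - 1.0) * frac


@dataclass
class SpiralTrajectory:
    """Stack-of-spirals k-space trajectory.

    ``kx``/``ky`` have shape (n_interleaves, n_samples) in cycles/mm at the
    gradient raster; ``gradients`` holds the matching per-axis waveforms in
    mT/m.  ``kz`` holds the slice-encode values in cycles/mm; the same
    in-plane spiral is replayed for every slice encode.
    """

    kx: np.ndarray
    ky: np.ndarray
    gradients: np.ndarray  # (n_interleaves, n_samples, 2) mT/m
    kz: np.ndarray  # (n_encodes,) cycles/mm
    kmax: float
    raster_time: float  # microseconds
    rotation_angles: np.ndarray
    fov: tuple[float, float]
    slice_thickness: float

    @property
    def n_interleaves(self) -> int:
        return self.kx.shape[0]

    @property
    def n_samples(self) -> int:
        return self.kx.shape[1]

    @property
    def n_slice_encodes(self) -> int:
        return self.kz.shape[0]

    @property
    def readout_time(self) -> float:
        """Duration of one interleaf readout in ms."""
        return self.n_samples * self.raster_time * 1e-3

    @property
    def n_lines(self) -> int:
        """In-plane k-space lines per slice encode (== interleaves)."""
        return self.n_interleaves

    def line_samples(self, line: int) -> tuple[np.ndarray, np.ndarray]:
        """(kx, ky) sample positions of one in-plane line, cycles/mm."""
        return self.kx[line], self.ky[line]


@dataclass
class CartesianTrajectory:
    """Phase-encode line enumeration for the reference Cartesian sequence.

    ``kx`` holds the frequency-encode sample positions of one line and
    ``ky_lines`` the phase-encode value of each line, both in cycles/mm.
    """

    kx: np.ndarray  # (n_samples,)
    ky_lines: np.ndarray  # (n_lines,)
    line_order: np.ndarray  # acquisition order (indices into ky_lines)
    kz: np.ndarray
    fov: tuple[float, float]
    slice_thickness: float

    @property
    def n_lines(self) -> int:
        return self.ky_lines.shape[0]

    @property
    def n_samples(self) -> int:
        return self.kx.shape[0]

    def line_samples(self, line: int) -> tuple[np.ndarray, np.ndarray]:
        """(kx, ky) sample positions of the ``line``-th acquired line."""
        ky = self.ky_lines[self.line_order[line]]
        return self.kx, np.full_like(self.kx, ky)


def n_encoded_slices(params: SequenceParams) -> int:
    """Number of slice-encode partitions including slice oversampling."""
    return int(round(params.n_slices_recon * (1.0 + params.slice_oversampling)))


def _kz_values(n_encodes: int, slice_thickness: float) -> np.ndarray:
    dkz = 1.0 / (n_encodes * slice_thickness)
    return (np.arange(n_encodes) - n_encodes // 2) * dkz


def design_spiral_interleaf(
    params: SequenceParams,
    limits: GradientLimits | None = None,
    density_profile: DensityProfile | None = None,
) -> SpiralTrajectory:
    """Design a gradient-limited variable-density stack-of-spirals trajectory.

    The base interleaf is an Archimedean spiral whose radial pitch follows the
    variable-density profile; it is traversed at the highest speed allowed by
    the slew and amplitude limits by numerically integrating the arc-length
    ODE at the gradient raster.  The remaining interleaves are rotated copies
    (counter-clockwise, interleaf 0 starting along +kx).

    Raises
    ------
    InfeasibleReadoutError
        If kmax cannot be reached within ``params.readout_duration``.
    """
    limits = limits or GradientLimits()
    profile = density_profile or DensityProfile()
    kmax = params.kmax
    n_il = params.n_interleaves
    fov = params.fov[0]
    dt = limits.raster_ms
    vmax = GAMMA_BAR * limits.max_gradient  # cycles/mm/ms
    amax = GAMMA_BAR * limits.max_slew_mt_m_ms  # cycles/mm/ms^2

    # nominal adjacent-turn spacing; dr/dtheta = spacing(r) / 2pi
    base_spacing = n_il / fov

    def rprime(r: float) -> float:
        return base_spacing * profile.factor(r, kmax) / (2.0 * np.pi)

    max_samples = int(np.ceil(params.readout_duration / dt)) + 1

    def integrate(safety: float) -> np.ndarray:
        theta = 0.0
        r = 0.0
        v = 0.0
        ks = [(0.0, 0.0)]
        while r < kmax:
            if len(ks) > max_samples:
                raise InfeasibleReadoutError(
                    f"spiral cannot reach kmax={kmax:.4f}/mm within "
                    f"{params.readout_duration} ms under the gradient limits"
                )
            rp = rprime(r)
            # radius of curvature of the spiral r(theta)
            num = (r * r + rp * rp) ** 1.5
            den = r * r + 2.0 * rp * rp  # r'' term negligible for slow taper
            rho = num / den if den > 0 else rp / 2.0
            rho = max(rho, rp / 2.0)
            v_cap = min(safety * vmax, np.sqrt(safety * amax * rho))
            if v < v_cap:
                # tangential acceleration budget after centripetal demand
                a_t = np.sqrt(max((safety * amax) ** 2 - (v * v / rho) ** 2, 0.0))
                v = min(v + a_t * dt, v_cap)
            else:
                v = v_cap
            ds = v * dt
            dtheta = ds / np.sqrt(r * r + rp * rp) if (r > 0 or rp > 0) else 0.0
            theta += dtheta
            r = r + rprime(r) * dtheta
            ks.append((r * np.cos(theta), r * np.sin(theta)))
        return np.asarray(ks)

    # the continuous-time speed law is discretized at the raster, which can
    # overshoot the slew limit by a few percent; back the safety margin off
    # until the sampled waveform is within limits
    safety = 0.995
    for _ in range(12):
        base = integrate(safety)
        g_chk = np.diff(base, axis=0, prepend=base[:1]) / (GAMMA_BAR * dt)
        slew_chk = np.diff(g_chk, axis=0) / dt
        s_peak = np.linalg.norm(slew_chk, axis=1).max()
        g_peak = np.linalg.norm(g_chk, axis=1).max()
        excess = max(
            s_peak / limits.max_slew_mt_m_ms, g_peak / limits.max_gradient
        )
        if excess <= 1.0:
            break
        safety *= 0.985 / excess
    # (n_samples, 2)
    n_samp = base.shape[0]
    angles = 2.0 * np.pi * np.arange(n_il) / n_il
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    kx = cos_a[:, None] * base[:, 0] - sin_a[:, None] * base[:, 1]
    ky = sin_a[:, None] * base[:, 0] + cos_a[:, None] * base[:, 1]

    k = np.stack([kx, ky], axis=-1)
    grads = np.diff(k, axis=1, prepend=k[:, :1]) / (GAMMA_BAR * dt)

    n_enc = n_encoded_slices(params)
    kz = _kz_values(n_enc, params.slice_thickness)

    return SpiralTrajectory(
        kx=kx,
        ky=ky,
        gradients=grads,
        kz=kz,
        kmax=kmax,
        raster_time=limits.raster_time,
        rotation_angles=angles,
        fov=params.fov,
        slice_thickness=params.slice_thickness,
    )


def cartesian_trajectory(
    params: SequenceParams, order: str = "low-high"
) -> CartesianTrajectory:
    """Enumerate the phase-encode lines of the reference Cartesian sequence.

    ``order='low-high'`` acquires phase encodes from the k-space center
    outward (alternating signs); ``order='linear'`` sweeps bottom to top.
    """
    nx, ny = params.matrix
    dx = params.voxel_size
    dk = 1.0 / params.fov[0]
    kx = (np.arange(nx) - nx // 2) * dk
    ky_lines = (np.arange(ny) - ny // 2) * dk
    if order == "linear":
        line_order = np.arange(ny)
    elif order == "low-high":
        idx = np.argsort(np.abs(np.arange(ny) - ny // 2), kind="stable")
        line_order = idx
    else:
        raise ValueError(f"unknown phase-encode ordering {order!r}")
    n_enc = n_encoded_slices(params)
    kz = _kz_values(n_enc, params.slice_thickness)
    return CartesianTrajectory(
        kx=kx,
        ky_lines=ky_lines,
        line_order=line_order,
        kz=kz,
        fov=params.fov,
        slice_thickness=params.slice_thickness,
    )


def nominal_temporal_resolution(params: SequenceParams) -> float:
    """Nominal temporal resolution in ms.

    One heart-phase slot holds ``segmentation_factor`` k-space lines of
    ``n_flow_segments`` velocity-encoding segments each, i.e. the slot
    length is ``segmentation_factor * n_flow_segments * TR``.
    """
    return params.segmentation_factor * params.n_flow_segments * params.tr


def nominal_scan_time(params: SequenceParams) -> int:
    """Nominal scan time in cardiac (RR) intervals.

    One k-space line (all flow segments, all heart phases) is completed per
    cardiac cycle per segmentation unit; the line count is interleaves times
    slice-encode partitions (reconstructed slices inflated by the slice
    oversampling factor, rounded to the nearest integer).
    """
    n_enc = n_encoded_slices(params)
    return int(round(params.n_interleaves * n_enc / params.segmentation_factor))
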