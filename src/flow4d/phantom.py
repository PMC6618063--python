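"""Analytic pulsatile flow phantom used as ground truth for the pipeline.

The phantom is a beating-heart surrogate: a straight tube along the x axis
with a smooth chamber-shaped bulge in the middle.  Flow is axisymmetric and
constructed from a Stokes stream function, so it is exactly divergence free
and satisfies no-penetration at the wall; the instantaneous volume flux is
the same through every cross-section.  The flow waveform has a raised-cosine
systolic ejection lobe and two raised-cosine diastolic inflow lobes (E and A
waves), with the A wave in the final part of the cycle so that truncating
late diastole demonstrably loses volume.

Beat-to-beat variability follows the physiological pattern that heart-rate
variation lives almost entirely in diastole: for a beat of length ``rr`` the
waveform keeps systole fixed and stretches diastole relative to the mean RR
cycle.

Coordinates are right-handed, in mm, with the volume center at the origin;
voxel centers sit at ``(i + 0.5) * delta - FOV / 2`` (half-open voxel
convention, 0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "VolumeGrid",
    "AnalyticFlowField",
    "make_phantom",
    "sample_rr_intervals",
    "apply_background_offset",
    "sample_on_grid",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular image grid: shape, voxel size and the half-open coordinate map."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm

    @property
    def fov(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape, self.voxel_size))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        d = self.voxel_size[axis]
        return (np.arange(n) + 0.5) * d - n * d / 2.0

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def points(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array."""
        xs, ys, zs = self.meshgrid()
        return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, waveform, signal and variability parameters of the phantom.

    Geometry: the chamber is the bulged segment ``|x| <= chamber_half_length``
    with maximum radius ``chamber_radius``; inlet (x < 0) and outlet (x > 0)
    tubes of radius ``tube_radius`` extend to the volume edges.  The default
    stroke volume, cycle length and wave timings are desk-scale but
    physiologically shaped (systole ~35% of the cycle, biphasic diastolic
    filling with the A wave in the final 15%).
    """

    chamber_half_length: float = 60.0  # mm
    chamber_radius: float = 13.0  # mm
    tube_radius: float = 9.0  # mm
    stroke_volume_ml: float = 30.0  # net volume transported per cycle
    systolic_duration_ms: float = 320.0
    e_volume_ml: float = 10.0
    a_volume_ml: float = 5.0
    e_start_ms: float = 400.0
    e_duration_ms: float = 250.0
    a_duration_ms: float = 135.0
    rr_mean_ms: float = 900.0
    rr_sd_ms: float = 50.0
    magnitude_fluid: float = 1.0
    magnitude_static: float = 0.6
    magnitude_background: float = 0.0
    noise_rel_sd: float = 0.02  # image-domain complex noise SD / fluid magnitude
    resp_amplitude_mm: float = 3.0
    resp_period_ms: float = 4000.0
    static_inner_mm: float = 20.0  # static-tissue slabs at static_inner <= |y| <= static_outer
    static_outer_mm: float = 60.0
    venc: float = 120.0  # cm/s, used only to validate the no-wrap invariant
    background_poly: dict | None = None  # component -> degree-4 coefficient array

    def __post_init__(self) -> None:
        if self.tube_radius <= 0 or self.chamber_radius <= self.tube_radius:
            raise ValueError("chamber must be wider than the attached tubes")
        if self.chamber_half_length <= 0:
            raise ValueError("chamber_half_length must be positive")
        if self.stroke_volume_ml < 0:
            raise ValueError("stroke volume must be >= 0")
        if self.systolic_duration_ms >= self.rr_mean_ms:
            raise ValueError("systole must be shorter than the mean RR interval")
        if self.e_volume_ml < 0 or self.a_volume_ml < 0:
            raise ValueError("E-wave and A-wave volumes must be >= 0")
        if self.systolic_volume_ml < 0:
            raise ValueError(
                "E-wave and A-wave volumes must not exceed the stroke volume"
            )
        if self.stroke_volume_ml == 0 and (self.e_volume_ml or self.a_volume_ml):
            raise ValueError("zero stroke volume requires zero E and A volumes")
        if self.e_start_ms < self.systolic_duration_ms:
            raise ValueError("E wave must start after end systole")
        if self.e_start_ms + self.e_duration_ms > self.rr_mean_ms - self.a_duration_ms:
            raise ValueError("E and A waves overlap")
        peak = self.peak_speed()
        if peak > self.venc / 100.0 * 1.0 + 1e-12:
            raise ValueError(
                f"peak fluid speed {peak:.3f} m/s exceeds venc {self.venc / 100:.3f} m/s"
            )

    @property
    def systolic_volume_ml(self) -> float:
        """Volume of the systolic ejection lobe.

        The phantom walls are rigid (the field is divergence free), so the
        per-cycle transported volume splits into a systolic ejection lobe
        and the two diastolic filling lobes; ``stroke_volume_ml`` is their
        total, which is what any cross-section plane measures per cycle.
        """
        return self.stroke_volume_ml - self.e_volume_ml - self.a_volume_ml

    def peak_flux(self) -> float:
        """Largest instantaneous volume flux over the cycle, mm^3/ms."""
        lobes = [
            (self.systolic_volume_ml, self.systolic_duration_ms),
            (self.e_volume_ml, self.e_duration_ms),
            (self.a_volume_ml, self.a_duration_ms),
        ]
        if self.stroke_volume_ml == 0:
            return 0.0
        return max(2.0 * v * 1000.0 / d for v, d in lobes if d > 0)

    def peak_speed(self) -> float:
        """Peak fluid speed in m/s (axial velocity at the tube throat)."""
        q = self.peak_flux()  # mm^3/ms
        u = 3.0 * q / (np.pi * self.tube_radius**2)  # mm/ms = m/s
        return u


def _raised_cosine(t: np.ndarray, start: float, duration: float, volume_mm3: float):
    """Flux lobe integrating to ``volume_mm3`` over [start, start+duration]."""
    inside = (t >= start) & (t < start + duration)
    q = np.zeros_like(t, dtype=float)
    tt = (t[inside] - start) / duration
    q[inside] = (volume_mm3 / duration) * (1.0 - np.cos(2.0 * np.pi * tt))
    return q


def normalize_cycle_time(t, rr: float, rr_mean: float, t_sys: float):
    """Map time-since-R in a beat of length ``rr`` onto the mean cycle.

    Systole (t <= t_sys) is kept fixed; diastole is stretched linearly so the
    beat ends at ``rr_mean``.  (The same rule is applied by the retrospective
    gating stage; the phantom uses it to *generate* beat-to-beat variability,
    so gating exactly inverts the physiology.)
    """
    if rr <= t_sys or rr_mean <= t_sys:
        raise ValueError("RR interval must exceed the systolic duration")
    t = np.asarray(t, dtype=float)
    scale = (rr_mean - t_sys) / (rr - t_sys)
    return np.where(t <= t_sys, t, t_sys + (t - t_sys) * scale)


class AnalyticFlowField:
    """Evaluation contract of the phantom: velocity, magnitude and region masks.

    ``velocity(points, t, rr)`` returns m/s (== mm/ms); ``t`` is the time
    since the R wave of a beat of length ``rr`` (defaults to the mean RR).
    The field is periodic in the cycle.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec

    # -- geometry -----------------------------------------------------------
    def radius_profile(self, x: np.ndarray) -> np.ndarray:
        """Wall radius R(x): tube radius with a C-infinity chamber bump."""
        s = self.spec
        u = np.asarray(x, dtype=float) / s.chamber_half_length
        b = np.zeros_like(u)
        inside = np.abs(u) < 1.0
        with np.errstate(divide="ignore", over="ignore"):
            b[inside] = np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
        return s.tube_radius + (s.chamber_radius - s.tube_radius) * b

    def _radius_slope(self, x: np.ndarray) -> np.ndarray:
        s = self.spec
        L = s.chamber_half_length
        u = np.asarray(x, dtype=float) / L
        db = np.zeros_like(u)
        inside = np.abs(u) < 1.0
        ui = u[inside]
        w = 1.0 - ui**2
        db[inside] = np.exp(1.0 - 1.0 / w) * (-2.0 * ui / w**2) / L
        return (s.chamber_radius - s.tube_radius) * db

    def fluid_mask(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        rho = np.hypot(p[:, 1], p[:, 2])
        return rho < self.radius_profile(p[:, 0])

    def static_mask(self, points: np.ndarray) -> np.ndarray:
        s = self.spec
        p = np.atleast_2d(points)
        ay = np.abs(p[:, 1])
        return (ay >= s.static_inner_mm) & (ay <= s.static_outer_mm)

    def magnitude(self, points: np.ndarray) -> np.ndarray:
        s = self.spec
        p = np.atleast_2d(points)
        m = np.full(p.shape[0], s.magnitude_background, dtype=float)
        m[self.static_mask(p)] = s.magnitude_static
        m[self.fluid_mask(p)] = s.magnitude_fluid
        return m

    # -- time ---------------------------------------------------------------
    def flux(self, t, rr: float | None = None) -> np.ndarray:
        """Volume flux through any cross-section at time ``t``, in mm^3/ms.

        Flow is unidirectional (+x): systolic ejection and diastolic filling
        lobes all push fluid from inlet to outlet.
        """
        s = self.spec
        rr = s.rr_mean_ms if rr is None else rr
        t = np.mod(np.asarray(t, dtype=float), rr)
        tau = normalize_cycle_time(t, rr, s.rr_mean_ms, s.systolic_duration_ms)
        q = _raised_cosine(tau, 0.0, s.systolic_duration_ms, s.systolic_volume_ml * 1e3)
        q += _raised_cosine(tau, s.e_start_ms, s.e_duration_ms, s.e_volume_ml * 1e3)
        q += _raised_cosine(
            tau, s.rr_mean_ms - s.a_duration_ms, s.a_duration_ms, s.a_volume_ml * 1e3
        )
        return q

    # -- field --------------------------------------------------------------
    def velocity(self, points: np.ndarray, t, rr: float | None = None) -> np.ndarray:
        """Velocity vectors (m/s) at ``points`` (mm) and cycle time ``t`` (ms).

        Derived from the Stokes stream function
        ``psi = Q(t)/(2 pi) * S(rho / R(x))`` with
        ``S(eta) = 1 - (1 - eta^2)^3``, giving a quartic axial profile
        ``u_x = 3 Q / (pi R^2) (1 - eta^2)^2`` that vanishes with zero slope
        at the wall, and the radial component that keeps the field exactly
        divergence free for the varying wall radius R(x).
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q = float(self.flux(t, rr))
        v = np.zeros_like(p)
        if q == 0.0:
            return v
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        rho = np.hypot(y, z)
        R = self.radius_profile(x)
        Rp = self._radius_slope(x)
        eta = rho / R
        inside = eta < 1.0
        w = np.zeros_like(eta)
        w[inside] = (1.0 - eta[inside] ** 2) ** 2
        coef = 3.0 * q / (np.pi * R**2)  # mm/ms
        v[:, 0] = coef * w
        # radial component: u_rho = 3 Q R' / (pi R^2) * eta * (1 - eta^2)^2
        u_rho_over_rho = coef * Rp * w / R  # divide by rho folded into unit vec
        v[:, 1] = u_rho_over_rho * y
        v[:, 2] = u_rho_over_rho * z
        v[~inside] = 0.0
        return v

    def peak_speed(self) -> float:
        return self.spec.peak_speed()


def make_phantom(spec: PhantomSpec | None = None) -> AnalyticFlowField:
    """Build the analytic flow field; validates the spec invariants."""
    return AnalyticFlowField(spec or PhantomSpec())


def sample_rr_intervals(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` RR intervals (ms) from a truncated normal distribution.

    Truncation at ``mean - 3.5 sd`` (and symmetrically above) keeps every
    beat longer than any plausible systole; with sd = 0 all beats equal the
    mean.  Deterministic under ``seed``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n, float(mean))
    rr = rng.normal(mean, sd, size=n)
    return np.clip(rr, mean - 3.5 * sd, mean + 3.5 * sd)


# ---------------------------------------------------------------------------
# background phase offsets (what the eddy-current correction must remove)

def apply_background_offset(
    velocity: np.ndarray, coefficients: np.ndarray, grid: VolumeGrid
) -> np.ndarray:
    """Add a polynomial background velocity offset to a gridded field.

    ``velocity`` has shape (..., 3, nx, ny, nz) (leading time axis optional);
    ``coefficients`` has shape (3, n_terms) for a polynomial of total degree
    <= 4 evaluated on coordinates normalized to [-1, 1] over the grid.
    """
    from .corrections import polynomial_basis  # shared basis definition

    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.ndim != 2 or coefficients.shape[0] != 3:
        raise ValueError("coefficients must have shape (3, n_terms)")
    pts = grid.points()
    basis = polynomial_basis(pts, grid)  # (N, n_terms)
    if coefficients.shape[1] > basis.shape[1]:
        raise ValueError("polynomial degree exceeds 4")
    offset = basis[:, : coefficients.shape[1]] @ coefficients.T  # (N, 3)
    offset = offset.T.reshape((3,) + grid.shape)
    return velocity + offset


def sample_on_grid(
    field: AnalyticFlowField,
    grid: VolumeGrid,
    times,
    rr: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample magnitude and velocity on a grid at the given cycle times.

    Returns ``(magnitude (nx, ny, nz), velocity (n_t, 3, nx, ny, nz))``.
    """
    pts = grid.points()
    mag = field.magnitude(pts).reshape(grid.shape)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    vel = np.empty((times.size, 3) + grid.shape)
    for i, t in enumerate(times):
        v = field.velocity(pts, t, rr)
        vel[i] = v.T.reshape((3,) + grid.shape)
    return mag, vel
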