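"""Image reconstruction: gridding for spiral k-space, FFT for Cartesian,
phase-difference velocity maps and SNR maps.

The spiral route is standard convolution gridding: density compensation,
convolution with a Kaiser-Bessel kernel onto an oversampled Cartesian grid,
inverse FFT in-plane, deapodization by the kernel transform, an exact
inverse DFT along the slice encodes, and cropping of the slice-oversampled
region.  Image coordinates follow the half-open voxel convention
``(i + 0.5) * delta - FOV / 2``, applied as a phase ramp on the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .gating import BinnedKSpace
from .phantom import VolumeGrid
from .sequence import CartesianTrajectory, SequenceParams, SpiralTrajectory

__all__ = [
    "GriddingConfig",
    "VelocityVolumeSeries",
    "grid_reconstruct",
    "cartesian_reconstruct",
    "phase_difference_velocity",
    "compute_snr",
    "radial_density_weights",
    "voronoi_density_weights",
]


@dataclass(frozen=True)
class GriddingConfig:
    """Kaiser-Bessel gridding parameters."""

    kernel: str = "kaiser-bessel"
    kernel_width: int = 4  # grid cells
    oversampling: float = 1.5
    density_compensation: str = "analytic-radial"  # or "voronoi"

    def __post_init__(self) -> None:
        if self.kernel != "kaiser-bessel":
            raise ValueError("only the Kaiser-Bessel kernel is implemented")
        if self.oversampling < 1.0:
            raise ValueError("oversampling must be >= 1")
        if self.kernel_width < 2:
            raise ValueError("kernel width must be >= 2")

    @property
    def beta(self) -> float:
        """Kernel shape parameter (Beatty et al. choice)."""
        w, os = self.kernel_width, self.oversampling
        return np.pi * np.sqrt((w / os) ** 2 * (os - 0.5) ** 2 - 0.8)


@dataclass
class VelocityVolumeSeries:
    """Reconstructed magnitude and three-component velocity over the cycle.

    ``magnitude``: (n_frames, nx, ny, nz) a.u.;
    ``velocity``: (n_frames, 3, nx, ny, nz) m/s.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    voxel_size: tuple[float, float, float]  # mm
    frame_duration: float  # ms
    venc: float  # cm/s

    def __post_init__(self) -> None:
        if self.velocity.shape[0] != self.magnitude.shape[0]:
            raise ValueError("magnitude and velocity frame counts differ")
        if self.velocity.shape[1] != 3 or self.velocity.shape[2:] != self.magnitude.shape[1:]:
            raise ValueError("velocity must be (n_frames, 3, nx, ny, nz)")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(shape=self.magnitude.shape[1:], voxel_size=self.voxel_size)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel on |u| <= width/2 (grid-cell units)."""
    x = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=float)
    ok = x > 0
    out[ok] = i0(beta * np.sqrt(x[ok])) / width
    return out


def _kb_deapodization(n_out: int, n_grid: int, width: int, beta: float) -> np.ndarray:
    """Kernel transform sampled at the (half-voxel offset) image positions.

    Computed numerically (Riemann sum of the kernel's Fourier integral), which
    stays correct for any width/beta combination.
    """
    fine = 64
    u = (np.arange(width * fine) + 0.5) / fine - width / 2.0
    kb = _kb_kernel(u, width, beta)
    # the apodization profile lives on the (unshifted) grid pixel positions;
    # the half-voxel coordinate shift is a phase ramp on the samples and does
    # not move the kernel envelope
    pos = np.arange(n_out) - n_out // 2
    c = (kb[None, :] * np.cos(2.0 * np.pi * np.outer(pos, u) / n_grid)).sum(axis=1)
    return c / fine


def radial_density_weights(traj: SpiralTrajectory) -> np.ndarray:
    """Analytic radial density compensation, mm^-2 per sample.

    Each sample is weighted by the annulus area it covers along its
    interleaf, ``2 pi r dr / n_interleaves``; the first (center) sample gets
    the enclosed disk.  The radial increments follow the designed
    variable-density pitch, so the weights adapt to the density profile.
    """
    r = np.hypot(traj.kx[0], traj.ky[0])
    dr = np.abs(np.gradient(r))
    w = 2.0 * np.pi * r * dr / traj.n_interleaves
    w[0] = np.pi * (0.5 * (r[0] + r[1])) ** 2 / traj.n_interleaves
    return np.broadcast_to(w, traj.kx.shape).copy()


def voronoi_density_weights(traj: SpiralTrajectory) -> np.ndarray:
    """Voronoi-cell density compensation over the pooled interleaf samples.

    Unbounded or degenerate cells (trajectory start/end) fall back to the
    analytic radial weight.
    """
    from scipy.spatial import Voronoi

    pts = np.stack([traj.kx.ravel(), traj.ky.ravel()], axis=1)
    fallback = radial_density_weights(traj).ravel()
    uniq, inv = np.unique(pts.round(12), axis=0, return_inverse=True)
    vor = Voronoi(uniq)
    area_u = np.full(uniq.shape[0], -1.0)
    for i, reg_i in enumerate(vor.point_region):
        reg = vor.regions[reg_i]
        if -1 in reg or len(reg) < 3:
            continue
        poly = vor.vertices[reg]
        if np.any(np.hypot(poly[:, 0], poly[:, 1]) > traj.kmax * 1.2):
            continue
        x, y = poly[:, 0], poly[:, 1]
        area_u[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    w = area_u[inv]
    dup = np.bincount(inv)[inv]
    w = np.where(w > 0, w / dup, fallback)
    return w.reshape(traj.kx.shape)


def _grid_plane(
    samples: np.ndarray,
    kx: np.ndarray,
    ky: np.ndarray,
    weights: np.ndarray,
    fov: float,
    n_out: int,
    config: GriddingConfig,
) -> np.ndarray:
    """Density-compensated KB gridding of one kz plane -> complex image."""
    os = config.oversampling
    width = config.kernel_width
    beta = config.beta
    ng = int(np.ceil(os * n_out / 2.0) * 2)
    fov_os = ng * fov / n_out  # keeps the pixel size exactly fov/n_out
    delta = fov / n_out

    kxf, kyf = kx.ravel(), ky.ravel()
    # half-voxel shift of the image coordinate origin
    vals = (samples.ravel() * weights.ravel()) * np.exp(
        2j * np.pi * (kxf + kyf) * 0.5 * delta
    )
    u = kxf * fov_os + ng / 2.0
    v = kyf * fov_os + ng / 2.0

    grid = np.zeros((ng, ng), dtype=complex)
    half = width / 2.0
    ju = np.arange(int(np.ceil(-half)), int(np.floor(half)) + 2)
    base_u = np.floor(u).astype(int)
    base_v = np.floor(v).astype(int)
    for du in ju:
        gu = base_u + du
        wu = _kb_kernel(gu - u, width, beta)
        if not wu.any():
            continue
        for dv in ju:
            gv = base_v + dv
            wv = _kb_kernel(gv - v, width, beta)
            wgt = wu * wv
            nz = wgt > 0
            if not nz.any():
                continue
            np.add.at(
                grid,
                (np.mod(gu[nz], ng), np.mod(gv[nz], ng)),
                vals[nz] * wgt[nz],
            )

    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * ng * ng
    lo = ng // 2 - n_out // 2
    img = img[lo : lo + n_out, lo : lo + n_out]
    c = _kb_deapodization(n_out, ng, width, beta)
    img = img / np.outer(c, c)
    return img * delta * delta  # adjoint-NUDFT scale: sum_j w_j S_j e^{+2pi i k r}


def grid_reconstruct(
    binned: BinnedKSpace,
    traj: SpiralTrajectory,
    params: SequenceParams,
    config: GriddingConfig | None = None,
) -> np.ndarray:
    """Gridding reconstruction of binned stack-of-spirals k-space.

    Returns complex images of shape (n_frames, 4, nx, ny, n_slices_recon):
    in-plane gridding per kz encode, exact inverse DFT along the slice
    encodes, and cropping of the slice-oversampled partitions.
    """
    config = config or GriddingConfig()
    nf = binned.n_frames
    n_kz, n_lines, n_samp = binned.data.shape[2:]
    if (n_lines, n_samp, n_kz) != (traj.n_lines, traj.n_samples, traj.n_slice_encodes):
        raise ValueError("binned data layout does not match the trajectory")
    if config.density_compensation == "analytic-radial":
        weights = radial_density_weights(traj)
    elif config.density_compensation == "voronoi":
        weights = voronoi_density_weights(traj)
    else:
        raise ValueError(f"unknown density compensation {config.density_compensation!r}")

    n_out = params.matrix[0]
    fov = params.fov[0]
    n_rec = params.n_slices_recon
    dz = params.slice_thickness
    zc = (np.arange(n_kz) + 0.5 - n_kz / 2.0) * dz  # encoded slice positions
    lo = (n_kz - n_rec) // 2
    zc = zc[lo : lo + n_rec]
    # exact inverse DFT along the slice encodes
    fz = np.exp(2j * np.pi * np.outer(traj.kz, zc)) / n_kz  # (n_kz, n_rec)

    out = np.empty((nf, 4, n_out, n_out, n_rec), dtype=complex)
    for f in range(nf):
        for seg in range(4):
            planes = np.empty((n_kz, n_out, n_out), dtype=complex)
            for zi in range(n_kz):
                planes[zi] = _grid_plane(
                    binned.data[f, seg, zi],
                    traj.kx,
                    traj.ky,
                    weights,
                    fov,
                    n_out,
                    config,
                )
            out[f, seg] = np.tensordot(planes, fz, axes=(0, 0))
    return out


def cartesian_reconstruct(
    kspace: np.ndarray, params: SequenceParams
) -> np.ndarray:
    """Exact FFT reconstruction of fully sampled Cartesian k-space.

    ``kspace``: (..., nx, ny, n_kz) sampled at ``k = (m - n//2) / FOV`` per
    in-plane axis and the stack's kz encodes; returns images at the same
    half-open voxel coordinates as the phantom grid, cropped to
    ``n_slices_recon`` slices.  On grid-aligned samples this is the exact
    inverse DFT (gridding degenerates to it).
    """
    kspace = np.asarray(kspace, dtype=complex)
    nx, ny, n_kz = kspace.shape[-3:]
    n_rec = min(params.n_slices_recon, n_kz)
    # half-voxel phase ramps per axis
    kxv = (np.arange(nx) - nx // 2) / params.fov[0]
    kyv = (np.arange(ny) - ny // 2) / params.fov[1]
    ramp = np.exp(
        2j * np.pi * 0.5 * params.voxel_size * (kxv[:, None] + kyv[None, :])
    )
    shifted = kspace * ramp[..., None]
    img = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(shifted, axes=(-3, -2)), axes=(-3, -2)),
        axes=(-3, -2),
    )
    dz = params.slice_thickness
    dkz = 1.0 / (n_kz * dz)
    kzv = (np.arange(n_kz) - n_kz // 2) * dkz
    zc = (np.arange(n_kz) + 0.5 - n_kz / 2.0) * dz
    lo = (n_kz - n_rec) // 2
    zc = zc[lo : lo + n_rec]
    fz = np.exp(2j * np.pi * np.outer(kzv, zc)) / n_kz
    return np.tensordot(img, fz, axes=(-1, 0))


def phase_difference_velocity(
    segments: np.ndarray,
    venc: float,
    voxel_size: tuple[float, float, float],
    frame_duration: float,
) -> VelocityVolumeSeries:
    """Convert four-point segment images to velocity maps.

    ``segments``: complex (n_frames, 4, nx, ny, nz) ordered (ref, vx, vy,
    vz); velocity per component is ``venc * arg(S_d conj(S_ref)) / pi`` in
    m/s (``venc`` in cm/s), magnitude is ``|S_ref|``.  Out-of-range phases
    are left wrapped (no unwrapping).
    """
    segments = np.asarray(segments)
    if segments.ndim != 5 or segments.shape[1] != 4:
        raise ValueError("segments must be (n_frames, 4, nx, ny, nz)")
    ref = segments[:, 0]
    vel = np.angle(segments[:, 1:] * np.conj(ref[:, None])) * (venc / 100.0) / np.pi
    return VelocityVolumeSeries(
        magnitude=np.abs(ref),
        velocity=vel,
        voxel_size=tuple(voxel_size),
        frame_duration=frame_duration,
        venc=venc,
    )


def compute_snr(
    magnitude: np.ndarray, noise: np.ndarray, roi: np.ndarray
) -> tuple[float, float]:
    """SNR in a region of interest.

    The SNR map divides the magnitude by the standard deviation of a
    signal-free noise image; returns (mean, SD) of the map over the ROI.
    """
    noise_sd = float(np.std(noise))
    if noise_sd == 0:
        raise ValueError("noise image has zero standard deviation")
    snr_map = np.asarray(magnitude, dtype=float) / noise_sd
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != snr_map.shape or not roi.any():
        raise ValueError("ROI must be a non-empty mask matching the magnitude")
    return float(snr_map[roi].mean()), float(snr_map[roi].std())
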