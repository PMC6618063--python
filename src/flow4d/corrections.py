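"""Eddy-current background velocity correction.

Phase offsets from eddy currents appear as a smooth, time-invariant
background velocity.  They are removed by detecting static tissue (low
temporal variance of the speed, adequate magnitude), fitting a fourth-order
spatial polynomial per velocity component to the time-averaged velocity of
the static voxels, and subtracting the fitted polynomial from every frame.
Coordinates are normalized to [-1, 1] before building the basis for
conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .phantom import VolumeGrid
from .recon import VelocityVolumeSeries

__all__ = [
    "StaticTissueMask",
    "PolynomialModel",
    "POLY_DEGREE",
    "N_POLY_TERMS",
    "polynomial_basis",
    "detect_static_tissue",
    "fit_background",
    "subtract_background",
]

POLY_DEGREE = 4
#: number of monomials x^i y^j z^k with i + j + k <= 4
N_POLY_TERMS = 35

# exponent table in a fixed, degree-then-lexicographic order
_EXPONENTS: list[tuple[int, int, int]] = []
for deg in range(POLY_DEGREE + 1):
    for combo in combinations_with_replacement(range(3), deg):
        e = [0, 0, 0]
        for axis in combo:
            e[axis] += 1
        _EXPONENTS.append(tuple(e))
assert len(_EXPONENTS) == N_POLY_TERMS


def polynomial_basis(points: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Degree-4 monomial basis (N, 35) on coordinates scaled to [-1, 1].

    The normalization maps each grid half-extent to 1, making the basis
    well conditioned independently of FOV.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    half = np.array(grid.fov) / 2.0
    u = pts / half
    cols = [u[:, 0] ** i * u[:, 1] ** j * u[:, 2] ** k for i, j, k in _EXPONENTS]
    return np.stack(cols, axis=1)


@dataclass
class StaticTissueMask:
    """Boolean static-tissue volume plus the thresholds that produced it."""

    mask: np.ndarray
    sd_percentile: float
    sd_threshold: float
    magnitude_floor: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PolynomialModel:
    """Per-component degree-4 background polynomial (35 coefficients each)."""

    coefficients: np.ndarray  # (3, 35)
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, N_POLY_TERMS):
            raise ValueError(f"coefficients must be (3, {N_POLY_TERMS})")

    def evaluate(self) -> np.ndarray:
        """Background velocity (3, nx, ny, nz) on the model's grid."""
        basis = polynomial_basis(self.grid.points(), self.grid)
        vals = basis @ self.coefficients.T  # (N, 3)
        return vals.T.reshape((3,) + self.grid.shape)


def detect_static_tissue(
    series: VelocityVolumeSeries,
    sd_percentile: float = 25.0,
    magnitude_floor_frac: float = 0.10,
) -> StaticTissueMask:
    """Detect static tissue by low temporal variance of the speed.

    A voxel is static iff its temporal SD of speed is at or below the given
    percentile (computed over voxels whose time-averaged magnitude exceeds
    ``magnitude_floor_frac`` of the maximum) and its magnitude is above the
    floor.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames to assess temporal variance")
    mag_mean = series.magnitude.mean(axis=0)
    floor = magnitude_floor_frac * float(mag_mean.max())
    above = mag_mean >= floor
    if not above.any():
        raise ValueError("magnitude floor excludes every voxel")
    speed = np.linalg.norm(series.velocity, axis=1)  # (T, nx, ny, nz)
    sd = speed.std(axis=0)
    thresh = float(np.percentile(sd[above], sd_percentile))
    mask = above & (sd <= thresh)
    if not mask.any():
        raise ValueError("static-tissue detection produced an empty mask")
    return StaticTissueMask(
        mask=mask,
        sd_percentile=sd_percentile,
        sd_threshold=thresh,
        magnitude_floor=floor,
    )


def fit_background(
    series: VelocityVolumeSeries, mask: StaticTissueMask | np.ndarray
) -> PolynomialModel:
    """Least-squares degree-4 polynomial fit to static-tissue velocity.

    The fit target is the time-averaged velocity of the masked voxels, per
    component (the correction is time invariant: one polynomial per
    component applied to all frames).
    """
    m = mask.mask if isinstance(mask, StaticTissueMask) else np.asarray(mask, bool)
    grid = series.grid
    if m.shape != grid.shape:
        raise ValueError("mask shape does not match the series")
    n = int(m.sum())
    if n < N_POLY_TERMS:
        raise ValueError(
            f"need at least {N_POLY_TERMS} static voxels for a degree-4 fit, got {n}"
        )
    pts = grid.points()[m.ravel()]
    basis = polynomial_basis(pts, grid)
    rank = np.linalg.matrix_rank(basis)
    if rank < N_POLY_TERMS:
        raise ValueError(
            f"polynomial basis is rank deficient on the mask (rank {rank})"
        )
    vmean = series.velocity.mean(axis=0)  # (3, nx, ny, nz)
    target = vmean.reshape(3, -1)[:, m.ravel()].T  # (n, 3)
    coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
    return PolynomialModel(coefficients=coef.T, grid=grid)


def subtract_background(
    series: VelocityVolumeSeries, model: PolynomialModel
) -> VelocityVolumeSeries:
    """Subtract the evaluated polynomial from every frame (magnitude untouched)."""
    background = model.evaluate()
    return VelocityVolumeSeries(
        magnitude=series.magnitude,
        velocity=series.velocity - background[None],
        voxel_size=series.voxel_size,
        frame_duration=series.frame_duration,
        venc=series.venc,
    )
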