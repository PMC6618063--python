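"""Plane-based flow quantification: flow-rate curves, net volume, peaks.

A measurement plane is an axis-aligned slice with an in-plane boolean mask
and a unit normal; the instantaneous volume flow rate is the sum of the
through-plane velocity times the pixel area over the mask.  With velocity
in m/s and pixel area in mm^2 the product is directly in ml/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import VelocityVolumeSeries

__all__ = [
    "PlaneSegmentation",
    "FlowResult",
    "flow_rate_curve",
    "net_volume",
    "peaks",
    "analyze_plane",
]


@dataclass
class PlaneSegmentation:
    """Axis-aligned measurement plane.

    ``axis`` is the slice axis (0=x, 1=y, 2=z), ``index`` the slice, ``mask``
    the in-plane boolean lumen mask (shape = volume shape with ``axis``
    removed), and ``normal`` the unit normal (along ``axis``, either sign).
    """

    axis: int
    index: int
    mask: np.ndarray
    normal: np.ndarray
    pixel_area: float  # mm^2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector")
        if abs(self.normal[self.axis]) < 1.0 - 1e-9:
            raise ValueError("normal must be along the slice axis")
        if not self.mask.any():
            raise ValueError("plane mask is empty")
        if self.pixel_area <= 0:
            raise ValueError("pixel area must be positive")


@dataclass
class FlowResult:
    """Flow quantities of one plane over the cycle."""

    flow_rate: np.ndarray  # ml/s per frame
    net_volume: float  # ml per cycle
    peak_flow_rate: float  # ml/s
    peak_velocity: float  # m/s
    frame_duration: float  # ms


def _plane_velocity(series: VelocityVolumeSeries, plane: PlaneSegmentation):
    """Through-plane velocity (n_frames, n_mask_pixels) in m/s."""
    if plane.axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if not 0 <= plane.index < series.magnitude.shape[1 + plane.axis]:
        raise ValueError("plane lies outside the volume")
    v = np.take(series.velocity, plane.index, axis=2 + plane.axis)
    # v: (n_frames, 3, a, b); project on the normal
    vn = np.tensordot(v, plane.normal, axes=(1, 0))
    expect = series.magnitude.shape[1:]
    expect = tuple(n for i, n in enumerate(expect) if i != plane.axis)
    if plane.mask.shape != expect:
        raise ValueError("plane mask shape does not match the volume slice")
    return vn[:, plane.mask]


def flow_rate_curve(
    series: VelocityVolumeSeries, plane: PlaneSegmentation
) -> np.ndarray:
    """Volume flow rate through the plane per frame, ml/s."""
    vn = _plane_velocity(series, plane)
    return vn.sum(axis=1) * plane.pixel_area


def net_volume(flow_rate: np.ndarray, frame_duration: float) -> float:
    """Net volume per cycle (ml): rectangle-rule sum of the flow-rate curve."""
    return float(np.sum(flow_rate) * frame_duration * 1e-3)


def peaks(
    series: VelocityVolumeSeries, plane: PlaneSegmentation
) -> tuple[float, float]:
    """(peak flow rate ml/s, peak velocity m/s) over frames and mask pixels.

    Peak velocity is the maximum magnitude of the through-plane component
    (clinical venc-direction convention), not the speed.
    """
    vn = _plane_velocity(series, plane)
    q = vn.sum(axis=1) * plane.pixel_area
    return float(np.abs(q).max()), float(np.abs(vn).max())


def analyze_plane(
    series: VelocityVolumeSeries, plane: PlaneSegmentation
) -> FlowResult:
    """Full plane analysis: curve, net volume and peaks."""
    q = flow_rate_curve(series, plane)
    pq, pv = peaks(series, plane)
    return FlowResult(
        flow_rate=q,
        net_volume=net_volume(q, series.frame_duration),
        peak_flow_rate=pq,
        peak_velocity=pv,
        frame_duration=series.frame_duration,
    )
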