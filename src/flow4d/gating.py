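"""Retrospective cardiac gating: normalize beats and bin readouts into frames.

Every acquired readout carries its time since the R wave and the length of
its beat.  Beats are mapped onto one average cardiac cycle by keeping
systole fixed and linearly stretching diastole (heart-rate variability is
predominantly diastolic), after which readouts are hard-binned into
``n_frames`` equal frames of the mean cycle; duplicate hits are averaged
(complex mean) and empty bins are borrowed from the nearest filled frame of
the same k-space line and segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquire import KSpaceSampleSet

__all__ = ["GatingConfig", "BinnedKSpace", "normalize_cardiac_time", "bin_samples"]


@dataclass(frozen=True)
class GatingConfig:
    """Reconstruction frame count and the systole/diastole split.

    ``t_sys`` is the systolic duration in ms; if None it defaults to
    ``t_sys_frac`` of the mean RR interval (the scanner's sorter does not
    expose its split point, so this is configurable).
    """

    n_frames: int = 40
    t_sys: float | None = None
    t_sys_frac: float = 0.4
    binning: str = "nearest-frame"
    borrow_missing: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.binning != "nearest-frame":
            raise ValueError("only nearest-frame binning is implemented")
        if self.t_sys is not None and self.t_sys <= 0:
            raise ValueError("t_sys must be positive")
        if not 0.0 < self.t_sys_frac < 1.0:
            raise ValueError("t_sys_frac must be in (0, 1)")

    def systole_ms(self, rr_mean: float) -> float:
        return self.t_sys if self.t_sys is not None else self.t_sys_frac * rr_mean


def normalize_cardiac_time(t, rr: float, rr_mean: float, t_sys: float):
    """Map time-since-R onto the average cycle (systole fixed, diastole scaled).

    ``t <= t_sys`` is returned unchanged; later times are stretched by
    ``(rr_mean - t_sys) / (rr - t_sys)`` so the beat ends at ``rr_mean``.
    Output lies in ``[0, rr_mean)``.
    """
    if rr <= t_sys:
        raise ValueError(f"RR interval {rr} ms not longer than systole {t_sys} ms")
    if rr_mean <= t_sys:
        raise ValueError("mean RR interval must exceed the systolic duration")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= rr):
        raise ValueError("t must lie in [0, rr)")
    scale = (rr_mean - t_sys) / (rr - t_sys)
    out = np.where(t <= t_sys, t, t_sys + (t - t_sys) * scale)
    out = np.minimum(out, np.nextafter(rr_mean, 0.0))
    return out if out.ndim else float(out)


@dataclass
class BinnedKSpace:
    """Frame-binned k-space: (frame, segment, kz encode, line, sample)."""

    data: np.ndarray  # complex, (n_frames, 4, n_kz, n_lines, n_samples)
    counts: np.ndarray  # int, (n_frames, 4, n_kz, n_lines)
    rr_mean: float  # ms
    t_sys: float  # ms
    fill_fraction: float  # filled bins / total bins before borrowing
    n_borrowed: int

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_duration(self) -> float:
        """Duration of one reconstructed frame in ms."""
        return self.rr_mean / self.n_frames


def bin_samples(samples: KSpaceSampleSet, config: GatingConfig) -> BinnedKSpace:
    """Sort accepted readouts of a complete acquisition into cardiac frames.

    Each readout is assigned to frame
    ``floor(normalized_time / (rr_mean / n_frames))`` (clipped to the last
    frame); duplicates are complex-averaged.  Binning conserves samples: the
    hit counts sum to the number of accepted readouts.

    Raises
    ------
    ValueError
        If any (line, slice-encode, segment) tuple has no accepted readout.
    """
    if not samples.completeness():
        raise ValueError("sample set is incomplete: some k-space line has no data")
    traj = samples.trajectory
    nf = config.n_frames
    rr_mean = samples.rr_mean_accepted
    t_sys = config.systole_ms(rr_mean)
    shape = (nf, 4, traj.n_slice_encodes, traj.n_lines)
    acc = np.zeros(shape + (traj.n_samples,), dtype=complex)
    counts = np.zeros(shape, dtype=int)
    frame_len = rr_mean / nf
    for ev, row in zip(samples.events, samples.samples):
        if not ev.accepted:
            continue
        tau = normalize_cardiac_time(ev.t_since_r, ev.rr, rr_mean, t_sys)
        f = min(int(tau // frame_len), nf - 1)
        acc[f, ev.segment, ev.slice_encode, ev.line] += row
        counts[f, ev.segment, ev.slice_encode, ev.line] += 1

    filled = counts > 0
    fill_fraction = float(filled.mean())
    data = np.zeros_like(acc)
    np.divide(acc, counts[..., None], out=data, where=filled[..., None])

    n_borrowed = 0
    if config.borrow_missing and not filled.all():
        half = nf // 2
        for seg in range(4):
            for zi in range(shape[2]):
                for li in range(shape[3]):
                    col = filled[:, seg, zi, li]
                    if col.all():
                        continue
                    src = np.flatnonzero(col)
                    if src.size == 0:
                        raise ValueError(
                            f"no accepted samples for line {li}, encode {zi}, "
                            f"segment {seg}"
                        )
                    for f in np.flatnonzero(~col):
                        d = np.abs(src - f)
                        d = np.minimum(d, nf - d)  # cyclic frame distance
                        data[f, seg, zi, li] = data[src[np.argmin(d)], seg, zi, li]
                        n_borrowed += 1

    return BinnedKSpace(
        data=data,
        counts=counts,
        rr_mean=rr_mean,
        t_sys=t_sys,
        fill_fraction=fill_fraction,
        n_borrowed=n_borrowed,
    )
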