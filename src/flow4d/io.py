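"""File formats: NIfTI volumes, HDF5 k-space containers, JSON/CSV results.

Velocity series are written as one 4D NIfTI per quantity (magnitude and
_vx/_vy/_vz component files, cardiac frame on the 4th axis, voxel size in
the affine, frame duration in the time zoom) plus a single-file HDF5
container; k-space sample sets, binned k-space and trajectories go to HDF5.
All round trips are lossless for every field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .acquire import KSpaceSampleSet, ReadoutEvent
from .gating import BinnedKSpace
from .phantom import PhantomSpec, VolumeGrid
from .recon import VelocityVolumeSeries
from .sequence import SequenceParams, SpiralTrajectory

__all__ = [
    "FileFormatError",
    "write_velocity_series_nifti",
    "read_velocity_series_nifti",
    "write_velocity_series_h5",
    "read_velocity_series_h5",
    "write_mask_nifti",
    "read_mask_nifti",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "write_sample_set_h5",
    "read_sample_set_h5",
    "write_binned_h5",
    "read_binned_h5",
    "write_results_json",
    "load_phantom_spec_yaml",
    "save_phantom_spec_yaml",
]

_COMPONENT_SUFFIXES = ("_vx", "_vy", "_vz")


class FileFormatError(ValueError):
    """A file could not be parsed; the message carries path and reason."""


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_velocity_series_nifti(series: VelocityVolumeSeries, stem: str | Path) -> list[Path]:
    """Write magnitude + three component files ``<stem>_mag/_vx/_vy/_vz.nii``."""
    stem = Path(stem)
    aff = _affine(series.voxel_size)
    paths = []
    arrays = [series.magnitude] + [series.velocity[:, c] for c in range(3)]
    names = ["_mag"] + list(_COMPONENT_SUFFIXES)
    for arr, name in zip(arrays, names):
        img = nib.Nifti1Image(np.moveaxis(arr, 0, -1).astype(np.float64), aff)
        img.header.set_zooms(series.voxel_size + (series.frame_duration,))
        img.header["descrip"] = f"venc={series.venc}cm/s".encode()
        p = stem.parent / (stem.name + name + ".nii")
        nib.save(img, p)
        paths.append(p)
    return paths


def read_velocity_series_nifti(stem: str | Path) -> VelocityVolumeSeries:
    stem = Path(stem)
    arrays = []
    venc = None
    frame_duration = None
    voxel = None
    for name in ["_mag"] + list(_COMPONENT_SUFFIXES):
        p = stem.parent / (stem.name + name + ".nii")
        if not p.exists():
            raise FileFormatError(f"{p}: missing component file")
        img = nib.load(p)
        zooms = img.header.get_zooms()
        voxel = tuple(float(z) for z in zooms[:3])
        frame_duration = float(zooms[3])
        desc = bytes(img.header["descrip"]).rstrip(b"\x00").decode()
        venc = float(desc.split("=")[1].replace("cm/s", ""))
        arrays.append(np.moveaxis(np.asarray(img.dataobj), -1, 0))
    return VelocityVolumeSeries(
        magnitude=arrays[0],
        velocity=np.stack(arrays[1:], axis=1),
        voxel_size=voxel,
        frame_duration=frame_duration,
        venc=venc,
    )


def write_mask_nifti(mask: np.ndarray, voxel_size, path: str | Path) -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, path)
    return Path(path)


def read_mask_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise FileFormatError(f"{path}: {exc}") from exc
    return np.asarray(img.dataobj).astype(bool), tuple(
        float(z) for z in img.header.get_zooms()[:3]
    )


def write_velocity_series_h5(series: VelocityVolumeSeries, path: str | Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=series.magnitude)
        f.create_dataset("velocity", data=series.velocity)
        f.attrs["voxel_size"] = series.voxel_size
        f.attrs["frame_duration"] = series.frame_duration
        f.attrs["venc"] = series.venc
    return Path(path)


def read_velocity_series_h5(path: str | Path) -> VelocityVolumeSeries:
    try:
        with h5py.File(path, "r") as f:
            return VelocityVolumeSeries(
                magnitude=f["magnitude"][()],
                velocity=f["velocity"][()],
                voxel_size=tuple(f.attrs["voxel_size"]),
                frame_duration=float(f.attrs["frame_duration"]),
                venc=float(f.attrs["venc"]),
            )
    except (OSError, KeyError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_trajectory_h5(traj: SpiralTrajectory, path: str | Path) -> Path:
    with h5py.File(path, "w") as f:
        for name in ("kx", "ky", "kz", "gradients", "rotation_angles"):
            f.create_dataset(name, data=getattr(traj, name))
        f.attrs["kmax"] = traj.kmax
        f.attrs["raster_time"] = traj.raster_time
        f.attrs["fov"] = traj.fov
        f.attrs["slice_thickness"] = traj.slice_thickness
    return Path(path)


def read_trajectory_h5(path: str | Path) -> SpiralTrajectory:
    try:
        with h5py.File(path, "r") as f:
            return SpiralTrajectory(
                kx=f["kx"][()],
                ky=f["ky"][()],
                gradients=f["gradients"][()],
                kz=f["kz"][()],
                kmax=float(f.attrs["kmax"]),
                raster_time=float(f.attrs["raster_time"]),
                rotation_angles=f["rotation_angles"][()],
                fov=tuple(f.attrs["fov"]),
                slice_thickness=float(f.attrs["slice_thickness"]),
            )
    except (OSError, KeyError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


_EVENT_FIELDS = ("line", "slice_encode", "segment", "t_abs", "t_since_r", "rr",
                 "nav_position", "accepted")


def write_sample_set_h5(ss: KSpaceSampleSet, path: str | Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=ss.samples)
        for name in _EVENT_FIELDS:
            f.create_dataset(
                f"events/{name}", data=np.array([getattr(e, name) for e in ss.events])
            )
        f.attrs["noise_sd"] = ss.noise_sd
        f.attrs["seed"] = ss.seed
        f.attrs["n_beats_total"] = ss.n_beats_total
        f.attrs["n_beats_rejected"] = ss.n_beats_rejected
        f.attrs["rr_mean_accepted"] = ss.rr_mean_accepted
        f.attrs["params"] = json.dumps(dataclasses.asdict(ss.params))
    grp_path = Path(path).with_suffix(".traj.h5")
    write_trajectory_h5(ss.trajectory, grp_path)
    return Path(path)


def read_sample_set_h5(path: str | Path) -> KSpaceSampleSet:
    try:
        with h5py.File(path, "r") as f:
            cols = {n: f[f"events/{n}"][()] for n in _EVENT_FIELDS}
            n_ev = cols["line"].size
            events = [
                ReadoutEvent(
                    line=int(cols["line"][i]),
                    slice_encode=int(cols["slice_encode"][i]),
                    segment=int(cols["segment"][i]),
                    t_abs=float(cols["t_abs"][i]),
                    t_since_r=float(cols["t_since_r"][i]),
                    rr=float(cols["rr"][i]),
                    nav_position=float(cols["nav_position"][i]),
                    accepted=bool(cols["accepted"][i]),
                )
                for i in range(n_ev)
            ]
            pd = json.loads(f.attrs["params"])
            pd["fov"] = tuple(pd["fov"])
            pd["matrix"] = tuple(pd["matrix"])
            params = SequenceParams(**pd)
            ss = KSpaceSampleSet(
                events=events,
                samples=f["samples"][()],
                trajectory=read_trajectory_h5(Path(path).with_suffix(".traj.h5")),
                params=params,
                noise_sd=float(f.attrs["noise_sd"]),
                seed=int(f.attrs["seed"]),
                n_beats_total=int(f.attrs["n_beats_total"]),
                n_beats_rejected=int(f.attrs["n_beats_rejected"]),
                rr_mean_accepted=float(f.attrs["rr_mean_accepted"]),
            )
        return ss
    except (OSError, KeyError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_binned_h5(binned: BinnedKSpace, path: str | Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=binned.data)
        f.create_dataset("counts", data=binned.counts)
        f.attrs["rr_mean"] = binned.rr_mean
        f.attrs["t_sys"] = binned.t_sys
        f.attrs["fill_fraction"] = binned.fill_fraction
        f.attrs["n_borrowed"] = binned.n_borrowed
    return Path(path)


def read_binned_h5(path: str | Path) -> BinnedKSpace:
    try:
        with h5py.File(path, "r") as f:
            return BinnedKSpace(
                data=f["data"][()],
                counts=f["counts"][()],
                rr_mean=float(f.attrs["rr_mean"]),
                t_sys=float(f.attrs["t_sys"]),
                fill_fraction=float(f.attrs["fill_fraction"]),
                n_borrowed=int(f.attrs["n_borrowed"]),
            )
    except (OSError, KeyError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_results_json(results: dict, path: str | Path) -> Path:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(results, indent=2, default=default))
    return Path(path)


def save_phantom_spec_yaml(spec: PhantomSpec, path: str | Path) -> Path:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(spec)))
    return Path(path)


def load_phantom_spec_yaml(path: str | Path) -> PhantomSpec:
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    try:
        data = yaml.safe_load(path.read_text())
        return PhantomSpec(**data)
    except (yaml.YAMLError, TypeError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
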