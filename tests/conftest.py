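"""Shared fixtures: desk-scale phantoms, sequence parameters and one cached
end-to-end pipeline run that several tests inspect."""

from __future__ import annotations

import numpy as np
import pytest

from flow4d import (
    PhantomSpec,
    PipelineConfig,
    SequenceParams,
    VolumeGrid,
    design_spiral_interleaf,
    make_phantom,
    run_pipeline,
)
from flow4d.pipeline import desk_sequence_params, recon_grid


@pytest.fixture(scope="session")
def default_field():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_spec():
    """Phantom scaled to fit a 32^2 x 4-slice volume (FOV ~90 mm)."""
    return PhantomSpec(
        chamber_half_length=28.0,
        chamber_radius=11.0,
        tube_radius=7.0,
        stroke_volume_ml=12.0,
        e_volume_ml=4.0,
        a_volume_ml=2.0,
        static_inner_mm=14.0,
        static_outer_mm=38.0,
        resp_amplitude_mm=0.0,
        noise_rel_sd=0.0,
        rr_sd_ms=0.0,
    )


@pytest.fixture(scope="session")
def small_params():
    return desk_sequence_params(matrix=32, n_slices=4, slice_thickness=5.0)


@pytest.fixture(scope="session")
def small_traj(small_params):
    return design_spiral_interleaf(small_params)


@pytest.fixture(scope="session")
def e2e_result():
    """One full simulated examination at the desk scale (64^2 x 8, 20 frames)."""
    return run_pipeline(PipelineConfig(seed=11))


@pytest.fixture(scope="session")
def e2e_truth(e2e_result):
    """Ground truth matching the cached end-to-end run."""
    from flow4d.pipeline import ground_truth_series

    cfg = PipelineConfig(seed=11)
    field = make_phantom(cfg.phantom)
    grid = e2e_result.series.grid
    gt = ground_truth_series(field, grid, e2e_result.series.n_frames)
    return field, gt


def strict_fluid_roi(field, grid: VolumeGrid) -> np.ndarray:
    """Voxels that lie entirely inside the fluid region (all 8 corners)."""
    pts = grid.points()
    inside = np.ones(len(pts), bool)
    half = np.asarray(grid.voxel_size) / 2.0
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                inside &= field.fluid_mask(pts + np.array([sx, sy, sz]) * half)
    return inside.reshape(grid.shape)
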