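"""Voxel-domain cone-beam forward projector and its exact adjoint.

``forward_project`` integrates the volume along the ray to each detector
pixel with Joseph-style stepping (trilinear samples at a fixed step length,
default the minimum voxel spacing).  The operator is linear in the voxel
values and ``back_project`` implements its exact discrete adjoint, so
gradients propagate correctly through DRR generation during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import ScanGeometry, Volume, VolumeGrid

__all__ = ["RaySample", "forward_project", "back_project", "project_all"]


@dataclass
class RaySample:
    """A single source->pixel ray with its volume intersection interval."""

    origin: np.ndarray
    direction: np.ndarray
    t_near: float
    t_far: float


def _view_vectors(geometry: ScanGeometry, angle_index: int):
    o = geometry.source_position(angle_index)
    w = geometry.view_matrix(angle_index)
    u_axis, v_axis, beam = w
    center = o + geometry.sdd * beam
    u_mm = geometry.detector_u_mm()
    v_mm = geometry.detector_v_mm()
    pix00 = center + u_mm[0] * u_axis + v_mm[0] * v_axis
    du_vec = geometry.pixel_u * u_axis
    dv_vec = geometry.pixel_v * v_axis
    return o, pix00, du_vec, dv_vec


def forward_project(
    volume: Volume, geometry: ScanGeometry, angle_index: int, step: float | None = None
) -> np.ndarray:
    """Line-integral DRR (n_v, n_u) of ``volume`` for one gantry angle."""
    if not 0 <= angle_index < geometry.n_views:
        raise IndexError(f"angle_index {angle_index} out of range")
    if step is None:
        step = float(min(volume.grid.spacing))
    o, pix00, du_vec, dv_vec = _view_vectors(geometry, angle_index)
    out = np.zeros((geometry.n_v, geometry.n_u))
    _kernels.joseph_forward(
        np.ascontiguousarray(volume.values, dtype=np.float64),
        np.asarray(volume.grid.origin), np.asarray(volume.grid.spacing),
        o, pix00, du_vec, dv_vec, step, out,
    )
    return out


def back_project(
    grad_frame: np.ndarray, grid: VolumeGrid, geometry: ScanGeometry,
    angle_index: int, step: float | None = None, out: np.ndarray | None = None,
) -> np.ndarray:
    """Exact adjoint of ``forward_project`` (accumulates into ``out``)."""
    if step is None:
        step = float(min(grid.spacing))
    o, pix00, du_vec, dv_vec = _view_vectors(geometry, angle_index)
    if out is None:
        out = np.zeros(grid.shape)
    _kernels.joseph_adjoint(
        np.ascontiguousarray(grad_frame, dtype=np.float64),
        np.asarray(grid.origin), np.asarray(grid.spacing),
        o, pix00, du_vec, dv_vec, step, out,
    )
    return out


def project_all(volume: Volume, geometry: ScanGeometry, step: float | None = None) -> np.ndarray:
    """DRRs for every view of a static volume; (n_views, n_v, n_u)."""
    frames = np.empty((geometry.n_views, geometry.n_v, geometry.n_u))
    for k in range(geometry.n_views):
        frames[k] = forward_project(volume, geometry, k, step=step)
    return frames
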