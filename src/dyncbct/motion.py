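"""Low-rank respiratory motion model: MBC Gaussians, DVF composition, warping.

A deformation vector field is factorized as

    d_k(x, p) = sum_{i=1..3} w_{i,k}(p) * e_{i,k}(x),       k in {x, y, z},

where the nine motion-basis components (MBCs) ``e_{i,k}`` — three
coarse-to-fine spatial levels times three Cartesian directions — are signed
scalar fields represented by Gaussian kernels and voxelized with the
negative-permitting voxelizer, and the per-projection coefficients ``w`` come
from the motion encoder.  Each level holds one kernel set with shared
positions and a 3-channel signed amplitude (one channel per direction).

Bases live on a coarse ``mbc_grid`` (displacements vary smoothly) and are
trilinearly upsampled when composed onto the output grid.  Warping is
backward (pull): ``I(x, p) = I_ref(x + d(x, p))``.

Note the sign/scale gauge: replacing ``(w, e)`` by ``(-w, -e)`` leaves every
composed DVF unchanged, so solved traces are only determined up to a global
sign; evaluation utilities compare traces after a logged sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .gaussians import GaussianSet, voxelize, voxelize_vjp
from .geometry import DisplacementField, Volume, VolumeGrid

__all__ = [
    "MBCLevel",
    "MBCModel",
    "voxelize_mbcs",
    "compose_dvf",
    "compose_dvf_vjp",
    "warp",
    "warp_vjp",
    "normality_loss",
    "normality_loss_grad",
]

DIRECTIONS = ("x", "y", "z")


@dataclass
class MBCLevel:
    """One spatial level: shared kernel positions, 3-channel signed amplitude."""

    positions: np.ndarray  # (M, 3)
    channels: np.ndarray  # (M, 3) signed, one per Cartesian direction
    scales: np.ndarray  # (M, 3)
    quaternions: np.ndarray  # (M, 4)

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    def as_gaussian_set(self, direction: int) -> GaussianSet:
        return GaussianSet(
            self.positions, self.channels[:, direction], self.scales, self.quaternions
        )


@dataclass
class MBCModel:
    """Three-level motion-basis model voxelized on ``mbc_grid``."""

    levels: list[MBCLevel]
    mbc_grid: VolumeGrid

    def __post_init__(self) -> None:
        counts = [lv.count for lv in self.levels]
        if len(counts) == 3 and not (counts[0] < counts[1] < counts[2]):
            raise ValueError(f"level counts must increase (coarse to fine), got {counts}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def initialize(
        cls,
        mbc_grid: VolumeGrid,
        lattice_sizes: tuple[int, int, int] = (20, 22, 24),
        scale_factor: float = 1.0,
    ) -> "MBCModel":
        """Uniform lattices of M_i = n_i^3 kernels; zero amplitudes.

        Initial kernel scales are ``scale_factor`` times the lattice pitch of
        their level so neighbouring kernels overlap into smooth fields.
        """
        levels = []
        ext = np.asarray(mbc_grid.extent_mm)
        lo = np.asarray(mbc_grid.origin) - 0.5 * np.asarray(mbc_grid.spacing)
        for n in lattice_sizes:
            pitch = ext / n
            axes = [lo[a] + (np.arange(n) + 0.5) * pitch[a] for a in range(3)]
            mesh = np.meshgrid(*axes, indexing="ij")
            pos = np.stack([g.ravel() for g in mesh], axis=-1)
            m = pos.shape[0]
            quats = np.zeros((m, 4))
            quats[:, 0] = 1.0
            levels.append(
                MBCLevel(
                    pos,
                    np.zeros((m, 3)),
                    np.full((m, 3), scale_factor * float(np.mean(pitch))),
                    quats,
                )
            )
        return cls(levels, mbc_grid)


def voxelize_mbcs(model: MBCModel) -> np.ndarray:
    """Voxelize all basis fields; returns (n_levels, 3, nx, ny, nz) in mm."""
    shape = model.mbc_grid.shape
    out = np.zeros((model.n_levels, 3) + shape)
    for i, lv in enumerate(model.levels):
        for k in range(3):
            out[i, k] = voxelize(
                lv.as_gaussian_set(k), model.mbc_grid, allow_negative=True
            ).values
    return out


def _resample_to(field: np.ndarray, src: VolumeGrid, dst: VolumeGrid) -> np.ndarray:
    if src.same_as(dst):
        return field
    out = np.empty(dst.shape)
    _kernels.resample_forward(
        np.ascontiguousarray(field), np.asarray(src.origin), np.asarray(src.spacing),
        np.asarray(dst.origin), np.asarray(dst.spacing), out,
    )
    return out


def upsample_basis(basis: np.ndarray, src: VolumeGrid, dst: VolumeGrid) -> np.ndarray:
    """Trilinearly resample every basis field onto ``dst``."""
    n_lvl = basis.shape[0]
    out = np.empty((n_lvl, 3) + dst.shape)
    for i in range(n_lvl):
        for k in range(3):
            out[i, k] = _resample_to(basis[i, k], src, dst)
    return out


def compose_dvf(
    basis: np.ndarray, w: np.ndarray, basis_grid: VolumeGrid, out_grid: VolumeGrid
) -> DisplacementField:
    """Coefficient-weighted sum of basis fields, resampled to ``out_grid``.

    ``w`` is ordered (level1:x,y,z, level2:x,y,z, level3:x,y,z); the result
    is exactly linear in ``w``.
    """
    n_lvl = basis.shape[0]
    w = np.asarray(w, dtype=np.float64).reshape(n_lvl, 3)
    d_coarse = np.einsum("ik,ik...->k...", w, basis)
    vec = np.stack([_resample_to(d_coarse[k], basis_grid, out_grid) for k in range(3)], axis=-1)
    return DisplacementField(out_grid, vec)


def compose_dvf_vjp(
    grad_vec: np.ndarray,
    basis_up: np.ndarray,
    basis_grid: VolumeGrid,
    out_grid: VolumeGrid,
):
    """Gradients of a composed DVF w.r.t. coefficients and basis fields.

    ``basis_up`` is the basis already upsampled to ``out_grid`` (cached by the
    training loop).  Returns ``(grad_w (n_lvl, 3), grad_basis on basis_grid)``.
    """
    n_lvl = basis_up.shape[0]
    grad_w = np.einsum("ikabc,abck->ik", basis_up, grad_vec)
    grad_basis = np.zeros((n_lvl, 3) + basis_grid.shape)
    for k in range(3):
        g = np.ascontiguousarray(grad_vec[..., k])
        if basis_grid.same_as(out_grid):
            adj = g
        else:
            adj = np.zeros(basis_grid.shape)
            _kernels.resample_adjoint(
                g, basis_grid.n_x, basis_grid.n_y, basis_grid.n_z,
                np.asarray(basis_grid.origin), np.asarray(basis_grid.spacing),
                np.asarray(out_grid.origin), np.asarray(out_grid.spacing), adj,
            )
        for i in range(n_lvl):
            grad_basis[i, k] = adj  # scaled by w by the caller
    return grad_w, grad_basis


def warp(reference: Volume, dvf: DisplacementField) -> Volume:
    """Backward-warp: output(x) = reference sampled at x + d(x), edge-clamped."""
    if not reference.grid.same_as(dvf.grid):
        raise ValueError("dvf grid must match the reference grid")
    out = np.empty(reference.grid.shape)
    _kernels.warp_forward(
        np.ascontiguousarray(reference.values, dtype=np.float64),
        np.ascontiguousarray(dvf.vectors, dtype=np.float64),
        np.asarray(reference.grid.origin), np.asarray(reference.grid.spacing), out,
    )
    return Volume(reference.grid, out)


def warp_vjp(reference: Volume, dvf: DisplacementField, grad_out: np.ndarray):
    """Gradients of the warp w.r.t. reference values and DVF vectors."""
    grad_ref = np.zeros(reference.grid.shape)
    grad_vec = np.zeros(reference.grid.shape + (3,))
    _kernels.warp_backward(
        np.ascontiguousarray(reference.values, dtype=np.float64),
        np.ascontiguousarray(dvf.vectors, dtype=np.float64),
        np.asarray(reference.grid.origin), np.asarray(reference.grid.spacing),
        np.ascontiguousarray(grad_out, dtype=np.float64), grad_ref, grad_vec,
    )
    return grad_ref, grad_vec


def normality_loss(basis: np.ndarray) -> float:
    """Mean squared deviation of each basis' mean-square norm from 1.

    L = (1/9) sum_{i,k} (||e_{i,k}||^2 - 1)^2 with ||e||^2 the voxel mean of
    e^2 (grid-size independent); zero iff every basis has unit mean-square.
    """
    n_lvl = basis.shape[0]
    flat = basis.reshape(n_lvl * 3, -1)
    msq = (flat**2).mean(axis=1)
    return float(((msq - 1.0) ** 2).mean())


def normality_loss_grad(basis: np.ndarray) -> np.ndarray:
    n_lvl = basis.shape[0]
    flat = basis.reshape(n_lvl * 3, -1)
    msq = (flat**2).mean(axis=1)
    n_vox = flat.shape[1]
    g = (4.0 / (n_lvl * 3)) * (msq - 1.0)[:, None] * flat / n_vox
    return g.reshape(basis.shape)
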