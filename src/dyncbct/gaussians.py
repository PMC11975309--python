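"""Radiative Gaussian kernels: parameterization, voxelization, density control.

A scalar field is represented as a sum of anisotropic Gaussian kernels

    sigma(x) = sum_i rho_i * exp(-1/2 (x - p_i)^T Sigma_i^-1 (x - p_i)),

with the covariance parameterized as ``Sigma = R(q) diag(s^2) R(q)^T`` (scale
vector + unit quaternion) so it is symmetric positive definite by
construction.  Kernels are truncated where the Gaussian falls below 1e-3 of
its amplitude (Mahalanobis radius ~3.7, < 0.4% of the mass outside).
Reference-CBCT sets keep ``rho >= 0`` (projected after
each optimizer step); motion-basis sets are signed and voxelized with the
negative-permitting variant (``allow_negative=True``).

All operations expose hand-derived vector-Jacobian products so the training
loop can assemble exact gradients without an autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import Volume, VolumeGrid

__all__ = [
    "GaussianSet",
    "AdaptiveControlConfig",
    "quat_to_rot",
    "voxelize",
    "voxelize_vjp",
    "init_from_volume",
    "adaptive_control",
]

SCALE_MIN = 0.1  # mm
SCALE_MAX = 100.0  # mm

# kernels are truncated where exp(-q/2) falls below 1e-3 of the amplitude
TRUNC_Q = 2.0 * np.log(1000.0)
TRUNC_RADIUS = np.sqrt(TRUNC_Q)  # ~3.7 Mahalanobis units


@dataclass
class GaussianSet:
    """A set of M Gaussian kernels over world coordinates (mm)."""

    positions: np.ndarray  # (M, 3) mm
    densities: np.ndarray  # (M,) signed amplitude (attenuation per mm)
    scales: np.ndarray  # (M, 3) mm, > 0
    quaternions: np.ndarray  # (M, 4) (w, x, y, z), normalized on use

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.densities = np.asarray(self.densities, dtype=np.float64).ravel()
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=np.float64))
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, dtype=np.float64))

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "GaussianSet":
        return cls(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 3)), np.zeros((0, 4)))

    def copy(self) -> "GaussianSet":
        return GaussianSet(
            self.positions.copy(), self.densities.copy(),
            self.scales.copy(), self.quaternions.copy(),
        )

    def rotations(self) -> np.ndarray:
        return quat_to_rot(self.quaternions)

    def covariances(self) -> np.ndarray:
        r = self.rotations()
        d = self.scales**2
        return np.einsum("mij,mj,mkj->mik", r, d, r)

    def inverse_covariances(self) -> np.ndarray:
        r = self.rotations()
        d = 1.0 / self.scales**2
        return np.einsum("mij,mj,mkj->mik", r, d, r)


def quat_to_rot(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from (w, x, y, z) quaternions (normalized internally)."""
    q = np.atleast_2d(q)
    n = np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = (q / n).T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )


def _quat_rot_jacobian(q: np.ndarray) -> np.ndarray:
    """d R / d q for raw (unnormalized) quaternions; shape (M, 4, 3, 3)."""
    q = np.atleast_2d(q)
    n = np.linalg.norm(q, axis=1, keepdims=True)
    qh = q / n
    w, x, y, z = qh.T
    zero = np.zeros_like(w)
    # derivatives of R w.r.t. the *unit* quaternion components
    dR = np.empty((q.shape[0], 4, 3, 3))
    dR[:, 0] = 2 * np.stack(
        [
            np.stack([zero, -z, y], -1),
            np.stack([z, zero, -x], -1),
            np.stack([-y, x, zero], -1),
        ],
        axis=1,
    )
    dR[:, 1] = 2 * np.stack(
        [
            np.stack([zero, y, z], -1),
            np.stack([y, -2 * x, -w], -1),
            np.stack([z, w, -2 * x], -1),
        ],
        axis=1,
    )
    dR[:, 2] = 2 * np.stack(
        [
            np.stack([-2 * y, x, w], -1),
            np.stack([x, zero, z], -1),
            np.stack([-w, z, -2 * y], -1),
        ],
        axis=1,
    )
    dR[:, 3] = 2 * np.stack(
        [
            np.stack([-2 * z, -w, x], -1),
            np.stack([w, -2 * z, y], -1),
            np.stack([x, y, zero], -1),
        ],
        axis=1,
    )
    # chain through the normalization q_hat = q / |q|
    proj = (np.eye(4)[None] - qh[:, :, None] * qh[:, None, :]) / n[:, :, None]
    return np.einsum("mab,mbij->maij", proj, dR)


def cov_grad_to_params(gset: GaussianSet, grad_sigma: np.ndarray):
    """Map dL/dSigma (M,3,3, symmetric) to gradients on scales and quaternions."""
    r = gset.rotations()
    d = gset.scales**2
    rt_g_r = np.einsum("mia,mij,mjb->mab", r, grad_sigma, r)
    grad_s = 2.0 * gset.scales * np.einsum("maa->ma", rt_g_r)
    # dL/dR = 2 * grad_sigma @ R @ diag(s^2) for symmetric grad_sigma
    grad_r = 2.0 * np.einsum("mij,mjb,mb->mib", grad_sigma, r, d)
    djac = _quat_rot_jacobian(gset.quaternions)
    grad_q = np.einsum("mij,maij->ma", grad_r, djac)
    return grad_s, grad_q


def _half_extents(gset: GaussianSet) -> np.ndarray:
    # axis-aligned bounding half extent of the truncation ellipsoid
    cov = gset.covariances()
    return TRUNC_RADIUS * np.sqrt(np.maximum(np.einsum("maa->ma", cov), 0.0))


def voxelize(gset: GaussianSet, grid: VolumeGrid, allow_negative: bool = False) -> Volume:
    """Evaluate the truncated kernel sum at every voxel center.

    Kernels are cut off at Mahalanobis radius ~3.7, where the dropped tail
    is below 1e-3 of the kernel amplitude.

    With ``allow_negative=False`` negative sums clamp to zero (physical
    attenuation); the negative-permitting variant keeps signed values for
    motion-basis fields.
    """
    out = np.zeros(grid.shape, dtype=np.float64)
    if gset.count:
        _kernels.voxelize_fwd(
            gset.positions, gset.densities, gset.inverse_covariances(),
            _half_extents(gset),
            np.asarray(grid.origin), np.asarray(grid.spacing), out, TRUNC_Q,
        )
    if not allow_negative:
        out = np.maximum(out, 0.0)
    return Volume(grid, out)


def voxelize_vjp(
    gset: GaussianSet, grid: VolumeGrid, grad_vol: np.ndarray,
    allow_negative: bool = False, raw: np.ndarray | None = None,
):
    """Gradients of ``sum(grad_vol * voxelize(gset))`` w.r.t. kernel parameters.

    ``raw`` is the pre-clamp voxelization (required when clamping applies so
    the clamp subgradient can be honoured).  Returns a dict with keys
    ``positions, densities, scales, quaternions``.
    """
    if gset.count == 0:
        return {
            "positions": np.zeros((0, 3)), "densities": np.zeros(0),
            "scales": np.zeros((0, 3)), "quaternions": np.zeros((0, 4)),
        }
    g = np.asarray(grad_vol, dtype=np.float64)
    if not allow_negative:
        if raw is None:
            raise ValueError("clamped voxelize_vjp requires the pre-clamp volume")
        g = np.where(raw > 0.0, g, 0.0)
    inv_cov = gset.inverse_covariances()
    acc_e = np.zeros(gset.count)
    acc_gd = np.zeros((gset.count, 3))
    acc_gdd = np.zeros((gset.count, 6))
    _kernels.voxelize_bwd(
        gset.positions, gset.densities, inv_cov, _half_extents(gset),
        np.asarray(grid.origin), np.asarray(grid.spacing),
        np.ascontiguousarray(g), acc_e, acc_gd, acc_gdd, TRUNC_Q,
    )
    grad_rho = acc_e
    grad_pos = np.einsum("mij,mj->mi", inv_cov, acc_gd)
    s_mat = np.empty((gset.count, 3, 3))
    s_mat[:, 0, 0] = acc_gdd[:, 0]
    s_mat[:, 1, 1] = acc_gdd[:, 1]
    s_mat[:, 2, 2] = acc_gdd[:, 2]
    s_mat[:, 0, 1] = s_mat[:, 1, 0] = acc_gdd[:, 3]
    s_mat[:, 0, 2] = s_mat[:, 2, 0] = acc_gdd[:, 4]
    s_mat[:, 1, 2] = s_mat[:, 2, 1] = acc_gdd[:, 5]
    grad_sigma = 0.5 * np.einsum("mij,mjk,mkl->mil", inv_cov, s_mat, inv_cov)
    grad_s, grad_q = cov_grad_to_params(gset, grad_sigma)
    return {
        "positions": grad_pos, "densities": grad_rho,
        "scales": grad_s, "quaternions": grad_q,
    }


def init_from_volume(
    volume: Volume, m: int, scheme: str = "grid", density_floor: float = 1e-3
) -> GaussianSet:
    """Initialize kernels from a (motion-averaged) volume.

    ``grid`` scheme: ~M lattice points over the grid, amplitude sampled from
    the volume, air points (below ``density_floor``) dropped; initial scales
    are isotropic at the lattice pitch.  ``uniform`` scheme: full lattice with
    zero amplitudes (motion-basis initialization).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    grid = volume.grid
    if m > grid.n_voxels:
        raise ValueError(f"m={m} exceeds voxel count {grid.n_voxels}")
    if scheme not in ("grid", "uniform"):
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    ext = np.asarray(grid.extent_mm)
    c = (m / np.prod(ext)) ** (1.0 / 3.0)
    counts = np.maximum(1, np.round(ext * c).astype(int))
    pitch = ext / counts
    axes = [
        grid.origin[a] - 0.5 * grid.spacing[a] + (np.arange(counts[a]) + 0.5) * pitch[a]
        for a in range(3)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pos = np.stack([g.ravel() for g in mesh], axis=-1)
    n = pos.shape[0]
    scale0 = float(np.mean(pitch))
    if scheme == "uniform":
        rho = np.zeros(n)
    else:
        idx = grid.world_to_index(pos)
        from scipy.ndimage import map_coordinates

        rho = map_coordinates(volume.values, idx.T, order=1, mode="nearest")
        keep = rho >= density_floor
        pos, rho = pos[keep], rho[keep]
        n = pos.shape[0]
    quats = np.zeros((n, 4))
    quats[:, 0] = 1.0
    return GaussianSet(pos, rho, np.full((n, 3), scale0), quats)


@dataclass
class AdaptiveControlConfig:
    """Thresholds for prune / clone / split density control."""

    prune_eps: float = 2e-4  # amplitude below which a kernel is "empty"
    grad_thresh: float = 1e-5  # mean positional-gradient norm triggering densify
    grad_quantile: float | None = 0.9  # if set, threshold = this quantile of the
    # current gradient distribution (bounds growth to ~10% per control event)
    size_thresh: float = 6.0  # mm: smaller kernels clone, larger ones split
    clone_step: float = 1.0  # mm per unit gradient direction for the clone offset
    split_factor: float = 1.6
    max_count: int = 200_000


@dataclass
class GradAccumulator:
    """Running per-kernel positional-gradient statistics between control events."""

    norm_sum: np.ndarray
    vec_sum: np.ndarray
    steps: int = 0

    @classmethod
    def zeros(cls, count: int) -> "GradAccumulator":
        return cls(np.zeros(count), np.zeros((count, 3)), 0)

    def update(self, grad_positions: np.ndarray) -> None:
        self.norm_sum += np.linalg.norm(grad_positions, axis=1)
        self.vec_sum += grad_positions
        self.steps += 1

    def mean(self) -> np.ndarray:
        return self.norm_sum / max(self.steps, 1)


def adaptive_control(
    gset: GaussianSet, grad_accumulator: GradAccumulator, cfg: AdaptiveControlConfig
) -> tuple[GaussianSet, GradAccumulator]:
    """Prune empty kernels; clone small / split large high-gradient kernels.

    Cloned and split kernels (and their parents) have their amplitude halved
    so the represented field changes smoothly.  Gradient statistics reset.
    """
    if grad_accumulator.norm_sum.shape[0] != gset.count:
        raise ValueError("gradient accumulator is not aligned with the Gaussian set")
    keep = np.abs(gset.densities) >= cfg.prune_eps
    mean_grad = grad_accumulator.mean()[keep]
    mean_vec = (grad_accumulator.vec_sum / max(grad_accumulator.steps, 1))[keep]
    out = GaussianSet(
        gset.positions[keep], gset.densities[keep],
        gset.scales[keep], gset.quaternions[keep],
    )
    thresh = cfg.grad_thresh
    if cfg.grad_quantile is not None and out.count:
        thresh = max(thresh, float(np.quantile(mean_grad, cfg.grad_quantile)))
    densify = mean_grad >= thresh
    if out.count >= cfg.max_count:
        densify[:] = False
    small = out.scales.max(axis=1) < cfg.size_thresh
    clone_idx = np.where(densify & small)[0]
    split_idx = np.where(densify & ~small)[0]

    new_pos, new_rho, new_scale, new_quat = [], [], [], []
    if clone_idx.size:
        # clone: copy offset by one (descent) gradient step; both halved
        out.densities[clone_idx] *= 0.5
        direction = mean_vec[clone_idx]
        norm = np.linalg.norm(direction, axis=1, keepdims=True)
        offset = -cfg.clone_step * direction / np.maximum(norm, 1e-30)
        new_pos.append(out.positions[clone_idx] + offset)
        new_rho.append(out.densities[clone_idx])
        new_scale.append(out.scales[clone_idx])
        new_quat.append(out.quaternions[clone_idx])
    if split_idx.size:
        cov = GaussianSet(
            out.positions[split_idx], out.densities[split_idx],
            out.scales[split_idx], out.quaternions[split_idx],
        ).covariances()
        evals, evecs = np.linalg.eigh(cov)
        # largest eigenvalue axis; ties resolved toward the lowest axis index
        axis = evecs[:, :, -1]
        sigma = np.sqrt(evals[:, -1])
        shift = 0.5 * sigma[:, None] * axis
        out.densities[split_idx] *= 0.5
        out.scales[split_idx] /= cfg.split_factor
        parent_pos = out.positions[split_idx].copy()
        out.positions[split_idx] = parent_pos + shift
        new_pos.append(parent_pos - shift)
        new_rho.append(out.densities[split_idx])
        new_scale.append(out.scales[split_idx])
        new_quat.append(out.quaternions[split_idx])
    if new_pos:
        out = GaussianSet(
            np.vstack([out.positions] + new_pos),
            np.concatenate([out.densities] + new_rho),
            np.vstack([out.scales] + new_scale),
            np.vstack([out.quaternions] + new_quat),
        )
    return out, GradAccumulator.zeros(out.count)
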