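"""Three-stage joint optimization of reference anatomy, motion model, encoder.

Stage 1 fits the reference-frame Gaussians to all projections with no motion
model, rendering DRRs with the splatting rasterizer (batch of one random
projection per step) under an L1 + D-SSIM projection loss and a random-
subvolume total-variation regularizer, with periodic adaptive density
control.  Stages 2 and 3 then introduce the MBC Gaussians and the CNN motion
encoder and optimize all three components jointly through the
voxelize -> compose-DVF -> warp -> project chain, at half output resolution
in Stage 2 and full resolution in Stage 3 (classic coarse-to-fine
registration), adding the MBC normality regularizer.  The optimization flows
continuously: nothing is reloaded or reinitialized between stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
import numpy as np

from . import _kernels
from .encoder import MotionEncoder, MotionEncoderSpec, prepare_input
from .fdk import fdk_reconstruct
from .gaussians import (
    AdaptiveControlConfig,
    GaussianSet,
    GradAccumulator,
    adaptive_control,
    init_from_volume,
    voxelize,
    voxelize_vjp,
)
from .geometry import (
    DisplacementField,
    ProjectionSet,
    ScanGeometry,
    Volume,
    VolumeGrid,
)
from .losses import dssim_loss, l1_loss, tv_loss
from .motion import (
    MBCModel,
    normality_loss,
    normality_loss_grad,
    upsample_basis,
    voxelize_mbcs,
    warp,
    warp_vjp,
)
from .optim import Adam
from .projector import back_project, forward_project
from .splat import splat_project, splat_vjp

__all__ = [
    "LossWeights",
    "StageSchedule",
    "LearningRates",
    "ReconConfig",
    "DynamicReconstruction",
    "stage1_fit",
    "stage23_fit",
    "reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass
class LossWeights:
    lambda_ssim: float = 0.25
    lambda_tv: float = 0.05
    lambda_mbc: float = 1.0
    tv_subvolume: int = 32


@dataclass
class StageSchedule:
    stage1_epochs: int = 5000
    stage2_epochs: int = 1000  # 2000 for half-fan scans
    stage3_epochs: int = 1000
    batch1: int = 1
    batch2: int = 32
    batch3: int = 8
    densify_every: int = 100
    densify_start: int = 500
    densify_end: int = 4000


@dataclass
class LearningRates:
    # positions move in mm; the rate is scaled by the scene extent and
    # decayed exponentially within each stage (multi-resolution settling)
    positions: float = 3e-4
    position_decay: float = 0.1  # final/initial position-rate ratio per stage
    densities: float = 2e-4  # attenuation units per step (~1% of soft tissue)
    scales: float = 5e-3  # log-space: relative size change per step
    rotations: float = 1e-3
    mbc_channels: float = 1e-2
    mbc_positions: float = 5e-2
    mbc_scales: float = 5e-3  # log-space
    encoder: float = 1e-3


@dataclass
class ReconConfig:
    """Everything a reconstruction run needs besides the projections."""

    grid_shape: tuple[int, int, int] = (200, 200, 100)
    grid_spacing: float = 2.0
    m_reference: int = 50_000
    mbc_lattices: tuple[int, int, int] = (20, 22, 24)
    mbc_grid_factor: int = 4  # MBC grid resolution = output / factor per axis
    density_floor: float = 1e-3
    weights: LossWeights = field(default_factory=LossWeights)
    schedule: StageSchedule = field(default_factory=StageSchedule)
    lrs: LearningRates = field(default_factory=LearningRates)
    adaptive: AdaptiveControlConfig = field(default_factory=AdaptiveControlConfig)
    adaptive_stage1: bool = True
    adaptive_stage23: bool = False
    stage1_path: str = "splat"  # or "voxproj" for debugging operator parity
    stage2_detector_downsample: int = 2
    scale_max: float | None = None  # default: the reference lattice pitch
    fdk_apodization: str = "hann"
    seed: int = 0

    @classmethod
    def profile(cls, name: str, fan_mode: str = "full", **overrides) -> "ReconConfig":
        """Named presets: ``full`` (complete protocol) and ``desk`` (CPU scale)."""
        if name == "full":
            cfg = cls()
            if fan_mode == "half":
                cfg.schedule.stage2_epochs = 2000
        elif name == "desk":
            cfg = cls(
                grid_shape=(100, 100, 50),
                grid_spacing=2.0,
                m_reference=8000,
                mbc_lattices=(6, 8, 10),
                schedule=StageSchedule(
                    stage1_epochs=800, stage2_epochs=220, stage3_epochs=150
                ),
                adaptive=AdaptiveControlConfig(max_count=12_000),
            )
        else:
            raise ValueError(f"unknown profile {name!r}")
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def output_grid(self) -> VolumeGrid:
        return VolumeGrid.centered(self.grid_shape, self.grid_spacing)


def coarsen_grid(grid: VolumeGrid, factor: int) -> VolumeGrid:
    """Grid with the same physical center at 1/factor resolution per axis."""
    new_n = tuple(max(2, n // factor) for n in grid.shape)
    new_sp = tuple(s * factor for s in grid.spacing)
    center = tuple(o + (n - 1) / 2.0 * s for o, n, s in zip(grid.origin, grid.shape, grid.spacing))
    origin = tuple(c - (n - 1) / 2.0 * s for c, n, s in zip(center, new_n, new_sp))
    return VolumeGrid(*new_n, spacing=new_sp, origin=origin)


def _voxelize_raw(gset: GaussianSet, grid: VolumeGrid, dtype=np.float64) -> np.ndarray:
    """Pre-clamp voxelization; float32 halves the cost of the training path."""
    from . import _kernels
    from .gaussians import TRUNC_Q, _half_extents

    out = np.zeros(grid.shape, dtype=dtype)
    if gset.count:
        _kernels.voxelize_fwd(
            gset.positions.astype(dtype), gset.densities.astype(dtype),
            gset.inverse_covariances().astype(dtype),
            _half_extents(gset).astype(dtype),
            np.asarray(grid.origin, dtype=dtype), np.asarray(grid.spacing, dtype=dtype),
            out, dtype(TRUNC_Q),
        )
    return out


def _voxelize_vjp32(gset: GaussianSet, grid: VolumeGrid, grad_vol, raw=None,
                    allow_negative=False):
    """float32 version of the voxelize VJP for the training hot path."""
    from . import _kernels
    from .gaussians import TRUNC_Q, _half_extents, cov_grad_to_params

    f4 = np.float32
    g = np.asarray(grad_vol, dtype=f4)
    if not allow_negative:
        g = np.where(raw > 0.0, g, f4(0.0))
    inv_cov = gset.inverse_covariances()
    m = gset.count
    acc_e = np.zeros(m, f4)
    acc_gd = np.zeros((m, 3), f4)
    acc_gdd = np.zeros((m, 6), f4)
    _kernels.voxelize_bwd(
        gset.positions.astype(f4), gset.densities.astype(f4), inv_cov.astype(f4),
        _half_extents(gset).astype(f4),
        np.asarray(grid.origin, f4), np.asarray(grid.spacing, f4),
        np.ascontiguousarray(g), acc_e, acc_gd, acc_gdd, f4(TRUNC_Q),
    )
    acc_gd = acc_gd.astype(np.float64)
    acc_gdd = acc_gdd.astype(np.float64)
    grad_pos = np.einsum("mij,mj->mi", inv_cov, acc_gd)
    s_mat = np.empty((m, 3, 3))
    s_mat[:, 0, 0] = acc_gdd[:, 0]
    s_mat[:, 1, 1] = acc_gdd[:, 1]
    s_mat[:, 2, 2] = acc_gdd[:, 2]
    s_mat[:, 0, 1] = s_mat[:, 1, 0] = acc_gdd[:, 3]
    s_mat[:, 0, 2] = s_mat[:, 2, 0] = acc_gdd[:, 4]
    s_mat[:, 1, 2] = s_mat[:, 2, 1] = acc_gdd[:, 5]
    grad_sigma = 0.5 * np.einsum("mij,mjk,mkl->mil", inv_cov, s_mat, inv_cov)
    grad_s, grad_q = cov_grad_to_params(gset, grad_sigma)
    return {
        "positions": grad_pos, "densities": acc_e.astype(np.float64),
        "scales": grad_s, "quaternions": grad_q,
    }


def _random_subgrid(grid: VolumeGrid, d: int, rng) -> VolumeGrid:
    shape = tuple(min(d, n) for n in grid.shape)
    corner = [rng.integers(0, n - s + 1) for n, s in zip(grid.shape, shape)]
    origin = tuple(
        grid.origin[a] + corner[a] * grid.spacing[a] for a in range(3)
    )
    return VolumeGrid(*shape, spacing=grid.spacing, origin=origin)


def _ref_param_dict(gset: GaussianSet) -> dict[str, np.ndarray]:
    return {
        "positions": gset.positions, "densities": gset.densities,
        "scales": gset.scales, "quaternions": gset.quaternions,
    }


def _step_gaussians(opt: Adam, gset: GaussianSet, grads: dict, scale_max: float,
                    nonneg: bool) -> None:
    """Adam step with kernel scales optimized in log space (multiplicative
    size updates are far better conditioned than additive ones)."""
    grads = dict(grads)
    grads["scales"] = grads["scales"] * gset.scales
    log_s = np.log(gset.scales)
    params = _ref_param_dict(gset)
    params["scales"] = log_s
    opt.step(params, grads)
    gset.scales[:] = np.exp(log_s)
    _project_constraints(gset, scale_max, nonneg=nonneg)


def _project_constraints(gset: GaussianSet, scale_max: float, nonneg: bool) -> None:
    if nonneg:
        np.clip(gset.densities, 0.0, None, out=gset.densities)
    np.clip(gset.scales, 0.5, scale_max, out=gset.scales)


def _lattice_pitch(grid: VolumeGrid, m: int) -> float:
    ext = np.asarray(grid.extent_mm)
    return float(np.mean(ext / np.maximum(1, np.round(ext * (m / np.prod(ext)) ** (1 / 3)))))


def stage1_fit(
    pset: ProjectionSet,
    gset: GaussianSet,
    weights: LossWeights,
    schedule: StageSchedule,
    seed: int = 0,
    grid: VolumeGrid | None = None,
    lrs: LearningRates | None = None,
    adaptive: AdaptiveControlConfig | None = None,
    scale_max: float = 20.0,
    path: str = "splat",
    log: list | None = None,
) -> GaussianSet:
    """Fit the reference Gaussians to the motion-averaged projection data."""
    if pset.geometry.n_views == 0:
        raise ValueError("empty projection set")
    lrs = lrs or LearningRates()
    rng = np.random.default_rng(seed)
    geo = pset.geometry
    extent = float(np.mean(grid.extent_mm)) if grid is not None else 200.0
    opt = Adam({
        "positions": lrs.positions * extent, "densities": lrs.densities,
        "scales": lrs.scales, "quaternions": lrs.rotations,
    })
    accum = GradAccumulator.zeros(gset.count)
    n_ep = max(schedule.stage1_epochs, 1)
    for epoch in range(schedule.stage1_epochs):
        opt.lrs["positions"] = (
            lrs.positions * extent * lrs.position_decay ** (epoch / n_ep)
        )
        k = int(rng.integers(geo.n_views))
        target = pset.frames[k]
        if path == "splat":
            rendered = splat_project(gset, geo, k).image
        else:
            vol = voxelize(gset, grid)
            rendered = forward_project(vol, geo, k)
        l1, g1 = l1_loss(rendered, target)
        ds, gds = dssim_loss(rendered, target)
        grad_img = g1 + weights.lambda_ssim * gds
        if path == "splat":
            grads = splat_vjp(gset, geo, k, grad_img)
        else:
            gvol = back_project(grad_img, grid, geo, k)
            raw = _voxelize_raw(gset, grid)
            grads = voxelize_vjp(gset, grid, gvol, raw=raw)
        tv = 0.0
        if weights.lambda_tv > 0 and grid is not None:
            sub = _random_subgrid(grid, weights.tv_subvolume, rng)
            raw = _voxelize_raw(gset, sub, dtype=np.float32)
            tv, gtv = tv_loss(np.maximum(raw, 0.0))
            tv_grads = _voxelize_vjp32(gset, sub, weights.lambda_tv * gtv, raw=raw)
            for key in grads:
                grads[key] = grads[key] + tv_grads[key]
        accum.update(grads["positions"])
        _step_gaussians(opt, gset, grads, scale_max, nonneg=True)
        if log is not None:
            log.append({"stage": 1, "epoch": epoch, "l1": l1, "dssim": ds, "tv": tv,
                        "count": gset.count})
        if (
            adaptive is not None
            and schedule.densify_start <= epoch <= schedule.densify_end
            and epoch > 0
            and epoch % schedule.densify_every == 0
        ):
            before = gset.count
            gset, accum = adaptive_control(gset, accum, adaptive)
            if gset.count != before:
                logger.info("adaptive control: %d -> %d kernels", before, gset.count)
            opt = Adam(opt.lrs)  # moments restart with the rebuilt set
    return gset


def _downsample_projections(pset: ProjectionSet, factor: int) -> ProjectionSet:
    geo = pset.geometry
    if factor <= 1 or geo.n_u % factor or geo.n_v % factor:
        return pset
    f = pset.frames
    f = f.reshape(f.shape[0], geo.n_v // factor, factor, geo.n_u // factor, factor).mean(
        axis=(2, 4)
    )
    geo2 = ScanGeometry(
        sad=geo.sad, sdd=geo.sdd, n_u=geo.n_u // factor, n_v=geo.n_v // factor,
        pixel_u=geo.pixel_u * factor, pixel_v=geo.pixel_v * factor,
        fan_mode=geo.fan_mode, detector_offset_u=geo.detector_offset_u,
        angles=geo.angles, times=geo.times,
    )
    return ProjectionSet(geo2, f)


@dataclass
class DynamicReconstruction:
    """Solved reference + motion model; materializes one volume per projection.

    ``coefficients`` are mean-centered (see the gauge note in stage23_fit);
    ``w_static`` holds the absorbed temporal-mean coefficients and
    ``reference_volume`` the correspondingly warped mean-state reference.
    Frames are materialized from the raw reference voxelization with the full
    deformation ``compose(w_k + w_static)`` so each frame involves a single
    interpolation.
    """

    reference_gaussians: GaussianSet
    reference_volume: Volume
    mbc: MBCModel
    encoder: MotionEncoder
    coefficients: np.ndarray  # (n_views, 9), zero temporal mean
    geometry: ScanGeometry
    grid: VolumeGrid
    basis: np.ndarray = None  # (3, 3, *mbc_grid.shape)
    w_static: np.ndarray = None  # (9,) absorbed mean coefficients
    base_volume: Volume = None  # raw reference voxelization (uncentered)
    _basis_up: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.geometry.n_views:
            raise ValueError("coefficient count must equal projection count")
        if self.basis is None:
            self.basis = voxelize_mbcs(self.mbc)
        if self.w_static is None:
            self.w_static = np.zeros(self.coefficients.shape[1])
        if self.base_volume is None:
            self.base_volume = self.reference_volume

    def _upsampled(self) -> np.ndarray:
        if self._basis_up is None:
            self._basis_up = upsample_basis(self.basis, self.mbc.mbc_grid, self.grid)
        return self._basis_up

    @property
    def n_frames(self) -> int:
        return self.geometry.n_views

    def dvf(self, k: int) -> DisplacementField:
        w = self.coefficients[k].reshape(3, 3)
        vec = np.einsum("ik,ik...->...k", w, self._upsampled())
        return DisplacementField(self.grid, vec)

    def frame(self, k: int) -> Volume:
        w = (self.coefficients[k] + self.w_static).reshape(3, 3)
        vec = np.einsum("ik,ik...->...k", w, self._upsampled())
        return warp(self.base_volume, DisplacementField(self.grid, vec))

    def materialize(self, indices=None):
        for k in indices if indices is not None else range(self.n_frames):
            yield self.frame(k)


def stage23_fit(
    pset: ProjectionSet,
    reference: GaussianSet,
    mbc: MBCModel,
    encoder: MotionEncoder,
    weights: LossWeights,
    schedule: StageSchedule,
    stage: int,
    seed: int = 0,
    out_grid: VolumeGrid | None = None,
    lrs: LearningRates | None = None,
    optimizers: tuple[Adam, Adam, Adam] | None = None,
    detector_downsample: int = 2,
    scale_max: float = 20.0,
    center_gauge: bool = True,
    log: list | None = None,
) -> DynamicReconstruction:
    """Jointly fit reference Gaussians, MBC Gaussians and the motion encoder."""
    if stage not in (2, 3):
        raise ValueError("stage must be 2 or 3")
    lrs = lrs or LearningRates()
    out_grid = out_grid or VolumeGrid.centered((100, 100, 50), 2.0)
    n_batch = schedule.batch2 if stage == 2 else schedule.batch3
    n_epochs = schedule.stage2_epochs if stage == 2 else schedule.stage3_epochs
    geo_full = pset.geometry
    if n_batch > geo_full.n_views:
        raise ValueError("batch size exceeds projection count")
    rng = np.random.default_rng(seed)

    if stage == 2:
        stage_grid = coarsen_grid(out_grid, 2)
        loss_pset = _downsample_projections(pset, detector_downsample)
    else:
        stage_grid = out_grid
        loss_pset = pset
    geo = loss_pset.geometry
    enc_inputs = np.stack([
        prepare_input(pset.frames[k], encoder.spec) for k in range(geo_full.n_views)
    ])

    extent = float(np.mean(out_grid.extent_mm))
    if optimizers is None:
        opt_ref = Adam({
            "positions": lrs.positions * extent, "densities": lrs.densities,
            "scales": lrs.scales, "quaternions": lrs.rotations,
        })
        opt_mbc = Adam(default_lr=lrs.mbc_channels)
        for i in range(mbc.n_levels):
            opt_mbc.lrs[f"lv{i}_positions"] = lrs.mbc_positions
            opt_mbc.lrs[f"lv{i}_scales"] = lrs.mbc_scales
            opt_mbc.lrs[f"lv{i}_quaternions"] = lrs.rotations
        opt_enc = Adam(default_lr=lrs.encoder)
    else:
        opt_ref, opt_mbc, opt_enc = optimizers

    order = rng.permutation(geo_full.n_views)
    cursor = 0
    mbc_params: dict[str, np.ndarray] = {}
    for i, lv in enumerate(mbc.levels):
        mbc_params[f"lv{i}_positions"] = lv.positions
        mbc_params[f"lv{i}_channels"] = lv.channels
        mbc_params[f"lv{i}_scales"] = lv.scales
        mbc_params[f"lv{i}_quaternions"] = lv.quaternions

    for epoch in range(n_epochs):
        opt_ref.lrs["positions"] = (
            lrs.positions * extent * lrs.position_decay ** (epoch / max(n_epochs, 1))
        )
        if cursor + n_batch > len(order):
            order = rng.permutation(geo_full.n_views)
            cursor = 0
        batch = order[cursor : cursor + n_batch]
        cursor += n_batch

        f4 = np.float32
        ref_raw = _voxelize_raw(reference, stage_grid, dtype=f4)
        ref_vals = np.maximum(ref_raw, 0.0)
        basis = voxelize_mbcs(mbc)
        basis_up = upsample_basis(basis, mbc.mbc_grid, stage_grid)
        basis_up32 = basis_up.astype(f4)

        w_batch, enc_cache = encoder.forward(enc_inputs[batch], training=True)
        grad_w = np.zeros_like(w_batch)
        grad_ref_vol = np.zeros(stage_grid.shape, f4)
        # coefficient-weighted DVF-gradient accumulators, one per basis field,
        # resampled to the MBC grid only once per step
        gvec_acc = np.zeros((mbc.n_levels, 3) + stage_grid.shape, f4)
        bu_flat = basis_up32.reshape(mbc.n_levels, 3, -1)
        origin32 = np.asarray(stage_grid.origin, f4)
        spacing32 = np.asarray(stage_grid.spacing, f4)
        step32 = f4(min(stage_grid.spacing))
        o32, pix32, du32, dv32 = [], [], [], []
        from .projector import _view_vectors

        loss_proj = 0.0
        for bi, k in enumerate(batch):
            w = w_batch[bi].reshape(3, 3).astype(f4)
            vec = np.einsum("ik,ik...->...k", w, basis_up32)
            warped = np.empty(stage_grid.shape, f4)
            _kernels.warp_forward(ref_vals, vec, origin32, spacing32, warped)
            o, pix00, du_vec, dv_vec = _view_vectors(geo, int(k))
            drr = np.zeros((geo.n_v, geo.n_u), f4)
            _kernels.joseph_forward(
                warped, origin32, spacing32, o.astype(f4), pix00.astype(f4),
                du_vec.astype(f4), dv_vec.astype(f4), step32, drr,
            )
            target = loss_pset.frames[k]
            l1, g1 = l1_loss(drr, target)
            ds, gds = dssim_loss(drr, target)
            loss_proj += (l1 + weights.lambda_ssim * ds) / n_batch
            grad_drr = ((g1 + weights.lambda_ssim * gds) / n_batch).astype(f4)
            grad_warped = np.zeros(stage_grid.shape, f4)
            _kernels.joseph_adjoint(
                np.ascontiguousarray(grad_drr), origin32, spacing32, o.astype(f4),
                pix00.astype(f4), du_vec.astype(f4), dv_vec.astype(f4), step32,
                grad_warped,
            )
            g_ref = np.zeros(stage_grid.shape, f4)
            g_vec = np.zeros(stage_grid.shape + (3,), f4)
            _kernels.warp_backward(
                ref_vals, vec, origin32, spacing32, grad_warped, g_ref, g_vec,
            )
            grad_ref_vol += g_ref
            grad_w[bi] = np.einsum("ikx,xk->ik", bu_flat, g_vec.reshape(-1, 3)).ravel()
            gvec_acc += w[:, :, None, None, None] * np.moveaxis(g_vec, -1, 0)[None]

        grad_basis = np.zeros_like(basis)
        for i in range(mbc.n_levels):
            for kdir in range(3):
                gk = np.ascontiguousarray(gvec_acc[i, kdir], dtype=np.float64)
                if mbc.mbc_grid.same_as(stage_grid):
                    grad_basis[i, kdir] = gk
                else:
                    _kernels.resample_adjoint(
                        gk, *mbc.mbc_grid.shape,
                        np.asarray(mbc.mbc_grid.origin), np.asarray(mbc.mbc_grid.spacing),
                        np.asarray(stage_grid.origin), np.asarray(stage_grid.spacing),
                        grad_basis[i, kdir],
                    )

        mbc_loss = normality_loss(basis)
        grad_basis += weights.lambda_mbc * normality_loss_grad(basis)

        tv = 0.0
        tv_grads = None
        if weights.lambda_tv > 0:
            sub = _random_subgrid(stage_grid, weights.tv_subvolume, rng)
            sub_raw = _voxelize_raw(reference, sub, dtype=f4)
            tv, gtv = tv_loss(np.maximum(sub_raw, 0.0))
            tv_grads = _voxelize_vjp32(reference, sub, weights.lambda_tv * gtv, raw=sub_raw)

        ref_grads = _voxelize_vjp32(reference, stage_grid, grad_ref_vol, raw=ref_raw)
        if tv_grads is not None:
            for key in ref_grads:
                ref_grads[key] = ref_grads[key] + tv_grads[key]

        mbc_grads: dict[str, np.ndarray] = {}
        for i, lv in enumerate(mbc.levels):
            gpos = np.zeros_like(lv.positions)
            gch = np.zeros_like(lv.channels)
            gsc = np.zeros_like(lv.scales)
            gq = np.zeros_like(lv.quaternions)
            for kdir in range(3):
                vjp = _voxelize_vjp32(
                    lv.as_gaussian_set(kdir), mbc.mbc_grid,
                    grad_basis[i, kdir], allow_negative=True,
                )
                gch[:, kdir] = vjp["densities"]
                gpos += vjp["positions"]
                gsc += vjp["scales"]
                gq += vjp["quaternions"]
            mbc_grads[f"lv{i}_positions"] = gpos
            mbc_grads[f"lv{i}_channels"] = gch
            mbc_grads[f"lv{i}_scales"] = gsc
            mbc_grads[f"lv{i}_quaternions"] = gq

        enc_grads = encoder.backward(enc_cache, grad_w)

        _step_gaussians(opt_ref, reference, ref_grads, scale_max, nonneg=True)
        for i in range(mbc.n_levels):
            g = mbc_grads[f"lv{i}_scales"]
            mbc_grads[f"lv{i}_scales"] = g * mbc.levels[i].scales
            log_s = np.log(mbc.levels[i].scales)
            mbc_params[f"lv{i}_scales"] = log_s
        opt_mbc.step(mbc_params, mbc_grads)
        for i, lv in enumerate(mbc.levels):
            lv.scales[:] = np.exp(mbc_params[f"lv{i}_scales"])
            np.clip(lv.scales, 2.0, 4.0 * scale_max, out=lv.scales)
            mbc_params[f"lv{i}_scales"] = lv.scales
        opt_enc.step(encoder.params, enc_grads)
        if log is not None:
            log.append({
                "stage": stage, "epoch": epoch, "proj": loss_proj,
                "mbc": mbc_loss, "tv": tv,
            })

    # assemble the solution at output resolution with inference-mode coefficients
    coeffs = np.stack([
        encoder.forward(enc_inputs[k : k + 1], training=False)[0][0]
        for k in range(geo_full.n_views)
    ])
    ref_out = Volume(out_grid, np.maximum(_voxelize_raw(reference, out_grid), 0.0))
    basis_out = voxelize_mbcs(mbc)
    if center_gauge:
        # Mean-field centering: the factorization w*e is only determined up to
        # a static deformation shared by every frame.  Absorb the temporal-mean
        # DVF into the reference so the reference corresponds to the scan's
        # mean motion state and the per-frame DVFs carry only actual motion.
        w_mean = coeffs.mean(axis=0)
        coeffs = coeffs - w_mean
        encoder.params["fc_b"] = encoder.params["fc_b"] - w_mean
        basis_up_out = upsample_basis(basis_out, mbc.mbc_grid, out_grid)
        d_mean = np.einsum(
            "ik,ik...->...k", w_mean.reshape(mbc.n_levels, 3), basis_up_out
        )
        ref_centered = warp(ref_out, DisplacementField(out_grid, d_mean))
        return DynamicReconstruction(
            reference_gaussians=reference, reference_volume=ref_centered, mbc=mbc,
            encoder=encoder, coefficients=coeffs, geometry=geo_full, grid=out_grid,
            basis=basis_out, w_static=w_mean, base_volume=ref_out,
        )
    return DynamicReconstruction(
        reference_gaussians=reference, reference_volume=ref_out, mbc=mbc,
        encoder=encoder, coefficients=coeffs, geometry=geo_full, grid=out_grid,
        basis=basis_out,
    )


def reconstruct(
    pset: ProjectionSet, config: ReconConfig, log_path: str | None = None
) -> DynamicReconstruction:
    """Full pipeline: FDK init -> Stage 1 -> Stage 2 -> Stage 3."""
    grid = config.output_grid()
    log: list = []
    logger.info("FDK initialization (%s apodization)", config.fdk_apodization)
    avg = fdk_reconstruct(pset, grid, apodization=config.fdk_apodization)
    avg = Volume(grid, np.maximum(avg.values, 0.0))

    reference = init_from_volume(
        avg, config.m_reference, scheme="grid", density_floor=config.density_floor
    )
    pitch = _lattice_pitch(grid, config.m_reference)
    reference.scales[:] = pitch / 2.0
    # cap kernel size at the lattice pitch: larger kernels add little detail
    # but their 3-sigma footprints dominate voxelization cost
    scale_max = config.scale_max if config.scale_max is not None else pitch
    logger.info("reference init: %d kernels, pitch %.1f mm", reference.count, pitch)

    mbc_grid = coarsen_grid(grid, config.mbc_grid_factor)
    mbc = MBCModel.initialize(mbc_grid, config.mbc_lattices)
    encoder = MotionEncoder(MotionEncoderSpec(), seed=config.seed)

    reference = stage1_fit(
        pset, reference, config.weights, config.schedule, seed=config.seed,
        grid=grid, lrs=config.lrs,
        adaptive=config.adaptive if config.adaptive_stage1 else None,
        scale_max=scale_max, path=config.stage1_path, log=log,
    )
    extent = float(np.mean(grid.extent_mm))
    opt_ref = Adam({
        "positions": config.lrs.positions * extent, "densities": config.lrs.densities,
        "scales": config.lrs.scales, "quaternions": config.lrs.rotations,
    })
    opt_mbc = Adam(default_lr=config.lrs.mbc_channels)
    for i in range(mbc.n_levels):
        opt_mbc.lrs[f"lv{i}_positions"] = config.lrs.mbc_positions
        opt_mbc.lrs[f"lv{i}_scales"] = config.lrs.mbc_scales
        opt_mbc.lrs[f"lv{i}_quaternions"] = config.lrs.rotations
    opt_enc = Adam(default_lr=config.lrs.encoder)
    optimizers = (opt_ref, opt_mbc, opt_enc)

    for stage in (2, 3):
        # gauge centering only on the final assembly: within the staged run the
        # optimizer state must see an unshifted encoder
        recon = stage23_fit(
            pset, reference, mbc, encoder, config.weights, config.schedule,
            stage=stage, seed=config.seed + stage, out_grid=grid, lrs=config.lrs,
            optimizers=optimizers,
            detector_downsample=config.stage2_detector_downsample,
            scale_max=scale_max, center_gauge=(stage == 3), log=log,
        )
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    recon.log = log
    return recon
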