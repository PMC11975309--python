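"""Quantitative evaluation: relative error, volumetric SSIM, COME, Dice,
contour propagation and trace comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import DisplacementField, Volume
from .motion import warp

__all__ = [
    "relative_error",
    "ssim_volume",
    "propagate_contour",
    "come",
    "dice",
    "TracePair",
    "localization_error",
    "pearson",
]

logger = logging.getLogger(__name__)


def relative_error(recon_frames, gt_frames, mask: np.ndarray | None = None) -> float:
    """Mean over frames of ||I - I_gt||_2 / ||I_gt||_2 (all voxels per frame)."""
    recon_frames = list(recon_frames)
    gt_frames = list(gt_frames)
    if len(recon_frames) != len(gt_frames):
        raise ValueError("frame counts differ")
    total = 0.0
    for rec, gt in zip(recon_frames, gt_frames):
        a = rec.values if isinstance(rec, Volume) else np.asarray(rec)
        b = gt.values if isinstance(gt, Volume) else np.asarray(gt)
        if a.shape != b.shape:
            raise ValueError("frame grids differ")
        if mask is not None:
            a = a[mask]
            b = b[mask]
        denom = np.sqrt((b.astype(np.float64) ** 2).sum())
        if denom == 0:
            raise ZeroDivisionError("ground-truth frame has zero norm")
        total += np.sqrt(((a - b).astype(np.float64) ** 2).sum()) / denom
    return total / len(recon_frames)


def ssim_volume(a: Volume, b: Volume, win_size: int = 7) -> float:
    """Mean local SSIM with a 3D cubic window; data range from ``b``."""
    if not a.grid.same_as(b.grid):
        raise ValueError("volume grids differ")
    drange = float(b.values.max() - b.values.min())
    if drange <= 0:
        drange = 1.0
    return float(
        structural_similarity(
            a.values.astype(np.float64), b.values.astype(np.float64),
            win_size=win_size, data_range=drange,
        )
    )


def propagate_contour(mask_ref: Volume | np.ndarray, dvf: DisplacementField) -> np.ndarray:
    """Warp a binary mask (as float) with a frame's DVF and re-threshold at 0.5."""
    if isinstance(mask_ref, Volume):
        vol = Volume(mask_ref.grid, mask_ref.values.astype(np.float64))
    else:
        vol = Volume(dvf.grid, np.asarray(mask_ref, dtype=np.float64))
    warped = warp(vol, dvf)
    return warped.values >= 0.5


def _com_world(mask: np.ndarray, grid) -> np.ndarray:
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return np.asarray(grid.origin) + idx.mean(axis=0) * np.asarray(grid.spacing)


def come(mask_a: np.ndarray, mask_b: np.ndarray, grid) -> float:
    """Center-of-mass distance between two binary structures, in mm."""
    return float(np.linalg.norm(_com_world(mask_a, grid) - _com_world(mask_b, grid)))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); defined as 1 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        logger.warning("dice of two empty masks; defining as 1.0")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / (na + nb))


def reference_state_index(recon, stride: int = 2) -> int:
    """Frame whose solved DVF is smallest: the reconstruction's own
    estimate of which motion state the reference anatomy corresponds to."""
    mags = [recon.dvf(k).max_magnitude() for k in range(0, recon.n_frames, stride)]
    return stride * int(np.argmin(mags))


def threshold_contour(values: np.ndarray, region: np.ndarray) -> np.ndarray:
    """50% threshold of ``values`` inside ``region`` (a dilated bounding
    region standing in for a manual contouring step), reduced to the largest
    connected component."""
    from scipy.ndimage import label

    lo = values[region].min()
    hi = values[region].max()
    mask = (values >= lo + 0.5 * (hi - lo)) & region
    labels, n = label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


@dataclass
class TracePair:
    """Solved vs reference 1D motion traces (mm), aligned in time."""

    times: np.ndarray
    solved: np.ndarray
    reference: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.solved = np.asarray(self.solved, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if not (len(self.times) == len(self.solved) == len(self.reference)):
            raise ValueError("trace lengths differ")
        if not (np.all(np.isfinite(self.solved)) and np.all(np.isfinite(self.reference))):
            raise ValueError("traces must be finite")


def _gauge_align(tp: TracePair) -> tuple[np.ndarray, bool]:
    """Flip the solved trace's sign if that improves correlation (MBC gauge)."""
    s = tp.solved - tp.solved.mean()
    r = tp.reference - tp.reference.mean()
    flip = float(np.dot(s, r)) < 0.0
    if flip:
        logger.info("trace sign-gauge flip applied for %s", tp.label or "trace")
    return (-tp.solved if flip else tp.solved), flip


def localization_error(tp: TracePair, allow_sign_flip: bool = True):
    """Mean and sd of |solved - reference| in mm (isocenter scale)."""
    solved = _gauge_align(tp)[0] if allow_sign_flip else tp.solved
    err = np.abs(solved - tp.reference)
    return float(err.mean()), float(err.std())


def pearson(tp: TracePair, allow_sign_flip: bool = True) -> float:
    solved = _gauge_align(tp)[0] if allow_sign_flip else tp.solved
    s = solved - solved.mean()
    r = tp.reference - tp.reference.mean()
    denom = np.sqrt((s**2).sum() * (r**2).sum())
    if denom == 0:
        return 1.0 if np.allclose(solved, tp.reference) else 0.0
    return float((s * r).sum() / denom)
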