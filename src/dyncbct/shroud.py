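"""Amsterdam-Shroud (AS) trace extraction from projection stacks.

Each projection's intensity gradient along the superior-inferior detector
axis (v, aligned with world z) is summed over a lateral column band into one
line profile; the profiles of all projections, concatenated in time order,
form the AS image, in which high-contrast edges (mostly the diaphragm) trace
out the breathing motion.  ``extract_trace`` follows the dominant gradient
extremum per column with subpixel (parabolic) refinement and a continuity
constraint, and rescales detector mm to isocenter mm by sad/sdd.
"""

from __future__ import annotations

import logging

import numpy as np

from .geometry import ProjectionSet

__all__ = ["as_image", "extract_trace", "select_band", "projection_trace"]

logger = logging.getLogger(__name__)


def as_image(pset: ProjectionSet, column_band: tuple[int, int]) -> np.ndarray:
    """AS image (n_v - 1 rows x n_views columns) from a projection stack."""
    lo, hi = column_band
    if not (0 <= lo < hi <= pset.geometry.n_u):
        raise ValueError(f"column band {column_band} outside detector width")
    grad = np.diff(pset.frames, axis=1)  # SI forward difference along v
    return grad[:, :, lo:hi].sum(axis=2).T


def select_band(pset: ProjectionSet) -> tuple[int, int]:
    """Widest u-band whose temporal gradient variance exceeds half its max."""
    grad = np.diff(pset.frames, axis=1)
    var_u = grad.var(axis=0).sum(axis=0)  # temporal variance summed over v
    thresh = 0.5 * var_u.max()
    good = var_u >= thresh
    if not good.any():
        return 0, pset.geometry.n_u
    idx = np.where(good)[0]
    return int(idx.min()), int(idx.max()) + 1


def extract_trace(
    as_img: np.ndarray, pixel_v: float = 1.0, sad: float = 1.0, sdd: float = 1.0,
    continuity_rows: int = 15,
) -> np.ndarray:
    """Per-column subpixel edge position, in mm at the isocenter plane.

    Follows the dominant absolute-gradient extremum with a +-continuity_rows
    constraint between adjacent columns; all-zero columns carry the previous
    position forward (flagged in the log).
    """
    if not np.any(as_img):
        raise ValueError("AS image is identically zero")
    n_rows, n_cols = as_img.shape
    mag = np.abs(as_img)
    pos = np.empty(n_cols)
    prev = None
    carried = 0
    for c in range(n_cols):
        col = mag[:, c]
        if col.max() <= 0:
            pos[c] = prev if prev is not None else 0.0
            carried += 1
            continue
        if prev is None:
            r = int(np.argmax(col))
        else:
            lo = max(0, int(round(prev)) - continuity_rows)
            hi = min(n_rows, int(round(prev)) + continuity_rows + 1)
            r = lo + int(np.argmax(col[lo:hi]))
        # parabolic subpixel refinement around the extremum
        if 0 < r < n_rows - 1:
            y0, y1, y2 = col[r - 1], col[r], col[r + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        pos[c] = r + delta
        prev = pos[c]
    if carried:
        logger.warning("%d all-zero AS columns carried over", carried)
    return pos * pixel_v * (sad / sdd)


def projection_trace(pset: ProjectionSet, band: tuple[int, int] | None = None) -> np.ndarray:
    """Convenience: AS trace of a projection set in isocenter mm."""
    if band is None:
        band = select_band(pset)
    img = as_image(pset, band)
    geo = pset.geometry
    return extract_trace(img, pixel_v=geo.pixel_v, sad=geo.sad, sdd=geo.sdd)
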