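"""FDK (Feldkamp-Davis-Kress) filtered backprojection for initialization.

Cosine-weighted, ramp-filtered (Ram-Lak, optional Hann apodization)
backprojection with distance weighting on the flat detector rescaled to the
isocenter plane.  Short-scan arcs get Parker weighting; half-fan (laterally
offset detector) inputs get a smooth sinusoidal redundancy weight over the
overlap band before filtering.  Used to build the motion-averaged volume that
seeds the reference Gaussians.
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels
from .geometry import ProjectionSet, Volume, VolumeGrid

__all__ = ["fdk_reconstruct", "ramp_kernel"]

logger = logging.getLogger(__name__)


def ramp_kernel(n: int, pitch: float) -> np.ndarray:
    """Band-limited Ram-Lak kernel (Kak & Slaney) of length 2n-1."""
    idx = np.arange(-(n - 1), n)
    h = np.zeros_like(idx, dtype=np.float64)
    h[idx == 0] = 1.0 / (4.0 * pitch**2)
    odd = idx % 2 != 0
    h[odd] = -1.0 / (np.pi * idx[odd] * pitch) ** 2
    return h


def _filter_rows(frames: np.ndarray, pitch: float, apodization: str) -> np.ndarray:
    n_u = frames.shape[-1]
    h = ramp_kernel(n_u, pitch)
    size = int(2 ** np.ceil(np.log2(2 * n_u)))
    hf = np.fft.rfft(h, size)
    if apodization == "hann":
        freq = np.fft.rfftfreq(size)
        hf = hf * 0.5 * (1 + np.cos(2 * np.pi * freq))
    elif apodization != "ramlak":
        raise ValueError(f"unknown apodization {apodization!r}")
    spec = np.fft.rfft(frames, size, axis=-1)
    full = np.fft.irfft(spec * hf, size, axis=-1)
    # the fan-beam FBP formula convolves with h/2 (Kak & Slaney eq. 3.87)
    return full[..., n_u - 1 : 2 * n_u - 1] * (0.5 * pitch)


def _parker_weights(angles_rad: np.ndarray, fan_half: float, gamma: np.ndarray):
    """Parker (1982) redundancy weights for a short scan of pi + 2*fan_half."""
    beta = angles_rad - angles_rad.min()
    g = gamma[None, :]
    b = beta[:, None]
    w = np.ones((len(beta), gamma.size))
    lo = b < 2 * (fan_half - g)
    w_lo = np.sin(np.pi / 4 * b / np.maximum(fan_half - g, 1e-9)) ** 2
    hi = b > np.pi - 2 * g
    w_hi = np.sin(np.pi / 4 * (np.pi + 2 * fan_half - b) / np.maximum(fan_half + g, 1e-9)) ** 2
    w = np.where(lo, w_lo, w)
    w = np.where(hi, w_hi, w)
    return np.clip(w, 0.0, 1.0)


def _overscan_weights(angles_rad: np.ndarray, fan_half: float, n_u: int):
    """Smooth end-taper weights for arcs between a short scan and a full turn."""
    beta = angles_rad - angles_rad.min()
    arc = beta.max()
    d = max(arc - np.pi - 2 * fan_half, 1e-6)
    w = np.ones_like(beta)
    head = beta < d
    w[head] = np.sin(np.pi / 2 * beta[head] / d) ** 2
    tail = beta > arc - d
    w[tail] = np.sin(np.pi / 2 * (arc - beta[tail]) / d) ** 2
    return np.repeat(w[:, None], n_u, axis=1)


def _halffan_weights(u_mm: np.ndarray, sdd: float) -> np.ndarray:
    """Smooth offset-detector redundancy weight (sinusoidal transition)."""
    overlap = min(abs(u_mm.min()), abs(u_mm.max()))
    if overlap <= 0:
        return np.ones_like(u_mm)
    sign = 1.0 if abs(u_mm.max()) >= abs(u_mm.min()) else -1.0
    x = sign * u_mm / overlap  # overlap band maps to [-1, 1]
    w = np.ones_like(u_mm)
    band = np.abs(x) <= 1.0
    w[band] = 0.5 * (1.0 + np.sin(np.pi / 2 * x[band]))
    w[sign * u_mm < -overlap] = 0.0
    return 2.0 * w


def fdk_reconstruct(
    pset: ProjectionSet, grid: VolumeGrid, apodization: str = "ramlak"
) -> Volume:
    """Reconstruct a (motion-averaged) volume from a circular cone-beam scan."""
    geo = pset.geometry
    if geo.n_views < 2:
        raise ValueError("FDK needs at least 2 projections to filter meaningfully")
    mag = geo.magnification
    u_det = geo.detector_u_mm()
    v_det = geo.detector_v_mm()
    # rescale detector coordinates to the isocenter plane
    a = u_det / mag
    b = v_det / mag
    da = geo.pixel_u / mag
    cos_w = geo.sad / np.sqrt(geo.sad**2 + a[None, :] ** 2 + b[:, None] ** 2)
    frames = pset.frames.astype(np.float64) * cos_w[None]

    angles_rad = np.deg2rad(geo.angles)
    arc = float(angles_rad.max() - angles_rad.min())
    dbeta_est = arc / max(geo.n_views - 1, 1)
    fan_half = float(np.arctan(max(abs(a.min()), abs(a.max())) / geo.sad))
    # a trajectory sampled up to 360 - dbeta still covers the full circle
    full_turn = arc + dbeta_est >= 2 * np.pi - np.deg2rad(1.0)
    if geo.fan_mode == "half":
        frames = frames * _halffan_weights(u_det, geo.sdd)[None, None, :]
    if not full_turn:
        if arc < np.pi + 2 * fan_half:
            logger.warning(
                "arc %.1f deg is below 180 deg + fan angle; reconstruction is "
                "quantitatively unreliable", np.rad2deg(arc),
            )
        gamma = np.arctan(a / geo.sad)
        if arc <= np.pi + 2 * fan_half + np.deg2rad(2.0):
            redundancy = _parker_weights(angles_rad, fan_half, gamma)
        else:
            redundancy = _overscan_weights(angles_rad, fan_half, geo.n_u)
        frames = frames * redundancy[:, None, :]

    filtered = _filter_rows(frames, da, apodization)

    # per-view integration weight: with the h/2 filter the parallel-equivalent
    # normalization is dbeta over a double-covered full turn and 2*dbeta over
    # a (Parker-weighted) single-covered short scan
    if geo.n_views > 1:
        dbeta = float(np.median(np.abs(np.diff(angles_rad))))
    else:
        dbeta = 2 * np.pi
    scale = dbeta if full_turn else 2.0 * dbeta
    view_weights = np.full(geo.n_views, scale)

    srcs = np.stack([geo.source_position(k) for k in range(geo.n_views)])
    rows = np.stack([geo.view_matrix(k) for k in range(geo.n_views)])
    out = np.zeros(grid.shape)
    u0 = float(u_det[0])
    v0 = float(v_det[0])
    _kernels.fdk_backproject(
        np.ascontiguousarray(filtered), srcs, rows, geo.sad, geo.sdd,
        u0, geo.pixel_u, v0, geo.pixel_v, view_weights,
        np.asarray(grid.origin), np.asarray(grid.spacing), out,
    )
    return Volume(grid, out)
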