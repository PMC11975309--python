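"""Training losses with closed-form gradients: L1, D-SSIM, subvolume TV."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["l1_loss", "dssim_loss", "tv_loss"]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = (11 - 1) / 2 / _SSIM_SIGMA  # 11x11 Gaussian window
_K1, _K2 = 0.01, 0.03


def l1_loss(a: np.ndarray, b: np.ndarray):
    """Mean absolute error and its gradient w.r.t. ``a``."""
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    diff = a - b
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad


def _win(x):
    return gaussian_filter(x, _SSIM_SIGMA, mode="reflect", truncate=_SSIM_TRUNCATE)


def dssim_loss(a: np.ndarray, b: np.ndarray):
    """Structural dissimilarity (1 - SSIM)/2 with gradient w.r.t. ``a``.

    SSIM uses an 11x11 Gaussian window (sigma 1.5); the dynamic range is
    taken from the observed range of the target ``b``.
    """
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    drange = float(b.max() - b.min())
    if drange <= 0:
        drange = 1.0
    c1 = (_K1 * drange) ** 2
    c2 = (_K2 * drange) ** 2
    mu_a = _win(a)
    mu_b = _win(b)
    saa = _win(a * a) - mu_a**2
    sbb = _win(b * b) - mu_b**2
    sab = _win(a * b) - mu_a * mu_b
    a1 = 2 * mu_a * mu_b + c1
    a2 = 2 * sab + c2
    b1 = mu_a**2 + mu_b**2 + c1
    b2 = saa + sbb + c2
    ssim_map = (a1 * a2) / (b1 * b2)
    loss = float((1.0 - ssim_map.mean()) / 2.0)

    n = a.size
    # partials of the per-pixel SSIM w.r.t. its local statistics
    d_mu = 2.0 * (mu_b * a2 - ssim_map * mu_a * b2) / (b1 * b2)
    d_saa = -ssim_map / b2
    d_sab = 2.0 * a1 / (b1 * b2)
    # chain through mu_a = G*a, saa = G*a^2 - mu_a^2, sab = G*(ab) - mu_a mu_b
    grad_ssim = (
        _win(d_mu - 2.0 * mu_a * d_saa - mu_b * d_sab)
        + 2.0 * a * _win(d_saa)
        + b * _win(d_sab)
    ) / n
    grad = -0.5 * grad_ssim
    return loss, grad


def tv_loss(subvolume: np.ndarray):
    """Mean anisotropic total variation of a cubic subvolume, with gradient.

    Average over the three axes of the mean absolute forward difference;
    zero for constants and homogeneous of degree one.
    """
    v = np.asarray(subvolume, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError("tv_loss expects a 3D subvolume")
    loss = 0.0
    grad = np.zeros_like(v)
    for axis in range(3):
        d = np.diff(v, axis=axis)
        if d.size == 0:
            continue
        loss += np.abs(d).mean() / 3.0
        s = np.sign(d) / (3.0 * d.size)
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        grad[tuple(sl_hi)] += s
        grad[tuple(sl_lo)] -= s
    return float(loss), grad
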