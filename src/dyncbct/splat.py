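"""Splatting-based X-ray rasterization of 3D Gaussian kernels.

Each 3D kernel is carried to ray space with the view transform ``W`` and a
local affine (first-order) approximation ``J`` of the projective mapping at
the kernel mean, giving ``Sigma_tilde = J W Sigma W^T J^T``.  Marginalizing
the ray coordinate leaves a 2D Gaussian on the detector with amplitude

    rho_hat = rho * sqrt(2*pi * det(Sigma_tilde) / det(Sigma_hat)),

the closed-form line integral through an unnormalized 3D Gaussian.  The
rendered image is the sum of these 2D Gaussians at pixel centers, each
rasterized only within its truncation footprint.  ``splat_vjp`` assembles exact
gradients for all kernel parameters through the full chain (including the
dependence of ``J`` on the kernel position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .gaussians import TRUNC_Q, TRUNC_RADIUS, GaussianSet, cov_grad_to_params
from .geometry import ScanGeometry

__all__ = ["SplatFrame", "splat_project", "splat_vjp"]

logger = logging.getLogger(__name__)

_T2_MIN = 1.0  # mm; kernels closer to / behind the source plane are skipped


@dataclass
class SplatFrame:
    """Projected 2D Gaussians plus the rendered detector image."""

    means: np.ndarray  # (M, 2) detector mm (u, v) from the piercing point
    covs: np.ndarray  # (M, 2, 2)
    amplitudes: np.ndarray  # (M,)
    image: np.ndarray  # (n_v, n_u)
    valid: np.ndarray  # (M,) kernels actually rasterized


def _project_kernels(gset: GaussianSet, geometry: ScanGeometry, angle_index: int):
    """Common forward geometry used by both the renderer and its VJP."""
    o = geometry.source_position(angle_index)
    w_mat = geometry.view_matrix(angle_index)
    f = geometry.sdd
    t = (gset.positions - o) @ w_mat.T  # (M, 3) camera coords
    valid = np.isfinite(t).all(axis=1) & (t[:, 2] > _T2_MIN)
    t_safe = np.where(valid[:, None], t, np.array([0.0, 0.0, geometry.sad]))
    t0, t1, t2 = t_safe.T
    m_norm = np.linalg.norm(t_safe, axis=1)
    u = f * t0 / t2
    v = f * t1 / t2
    jac = np.zeros((gset.count, 3, 3))
    jac[:, 0, 0] = f / t2
    jac[:, 0, 2] = -f * t0 / t2**2
    jac[:, 1, 1] = f / t2
    jac[:, 1, 2] = -f * t1 / t2**2
    jac[:, 2, 0] = t0 / m_norm
    jac[:, 2, 1] = t1 / m_norm
    jac[:, 2, 2] = t2 / m_norm
    k_mat = jac @ w_mat  # (M, 3, 3)
    sigma = gset.covariances()
    sigma_t = np.einsum("mij,mjk,mlk->mil", k_mat, sigma, k_mat)
    sigma_t = 0.5 * (sigma_t + sigma_t.transpose(0, 2, 1))
    sigma_h = sigma_t[:, :2, :2]
    det_t = np.linalg.det(sigma_t)
    det_h = sigma_h[:, 0, 0] * sigma_h[:, 1, 1] - sigma_h[:, 0, 1] ** 2
    good = np.isfinite(det_t) & (det_t > 0) & (det_h > 0)
    bad = valid & ~good
    if np.any(bad):
        logger.warning("skipping %d kernels with non-finite projected covariance", bad.sum())
    valid = valid & good
    det_t = np.where(valid, det_t, 1.0)
    det_h = np.where(valid, det_h, 1.0)
    amp = gset.densities * np.sqrt(2.0 * np.pi * det_t / det_h)
    amp = np.where(valid, amp, 0.0)
    return o, w_mat, t_safe, u, v, jac, k_mat, sigma, sigma_t, sigma_h, det_t, det_h, amp, valid


def _detector_grid(geometry: ScanGeometry):
    u0 = -(geometry.n_u - 1) / 2.0 * geometry.pixel_u + geometry.detector_offset_u
    v0 = -(geometry.n_v - 1) / 2.0 * geometry.pixel_v
    return u0, geometry.pixel_u, v0, geometry.pixel_v


def _inv2(sigma_h, det_h):
    inv = np.empty((sigma_h.shape[0], 3))
    inv[:, 0] = sigma_h[:, 1, 1] / det_h
    inv[:, 1] = -sigma_h[:, 0, 1] / det_h
    inv[:, 2] = sigma_h[:, 0, 0] / det_h
    return inv


def splat_project(gset: GaussianSet, geometry: ScanGeometry, angle_index: int) -> SplatFrame:
    """Rasterize the kernel set into a line-integral image for one view."""
    image = np.zeros((geometry.n_v, geometry.n_u))
    if gset.count == 0:
        return SplatFrame(np.zeros((0, 2)), np.zeros((0, 2, 2)), np.zeros(0), image,
                          np.zeros(0, dtype=bool))
    (_, _, _, u, v, _, _, _, _, sigma_h, _, det_h, amp, valid) = _project_kernels(
        gset, geometry, angle_index
    )
    phat = np.stack([u, v], axis=-1)
    inv2 = _inv2(sigma_h, det_h)
    half_extent = TRUNC_RADIUS * np.sqrt(
        np.maximum(np.stack([sigma_h[:, 0, 0], sigma_h[:, 1, 1]], -1), 0.0)
    )
    u0, du, v0, dv = _detector_grid(geometry)
    _kernels.splat_fwd(phat, inv2, amp, half_extent, u0, du, v0, dv, image, TRUNC_Q)
    return SplatFrame(phat, sigma_h.copy(), amp, image, valid)


def splat_vjp(
    gset: GaussianSet, geometry: ScanGeometry, angle_index: int, grad_image: np.ndarray
):
    """Exact parameter gradients of ``sum(grad_image * rendered_image)``."""
    if gset.count == 0:
        return {
            "positions": np.zeros((0, 3)), "densities": np.zeros(0),
            "scales": np.zeros((0, 3)), "quaternions": np.zeros((0, 4)),
        }
    (o, w_mat, t, u, v, jac, k_mat, sigma, sigma_t, sigma_h, det_t, det_h, amp, valid
     ) = _project_kernels(gset, geometry, angle_index)
    f = geometry.sdd
    phat = np.stack([u, v], axis=-1)
    inv2 = _inv2(sigma_h, det_h)
    half_extent = TRUNC_RADIUS * np.sqrt(
        np.maximum(np.stack([sigma_h[:, 0, 0], sigma_h[:, 1, 1]], -1), 0.0)
    )
    u0, du, v0, dv = _detector_grid(geometry)
    m = gset.count
    acc_e = np.zeros(m)
    acc_gd = np.zeros((m, 2))
    acc_gdd = np.zeros((m, 3))
    _kernels.splat_bwd(
        phat, inv2, amp, half_extent, u0, du, v0, dv,
        np.ascontiguousarray(np.asarray(grad_image, dtype=np.float64)),
        acc_e, acc_gd, acc_gdd, TRUNC_Q,
    )
    a_hat = np.empty((m, 2, 2))
    a_hat[:, 0, 0] = inv2[:, 0]
    a_hat[:, 0, 1] = a_hat[:, 1, 0] = inv2[:, 1]
    a_hat[:, 1, 1] = inv2[:, 2]
    s2 = np.empty((m, 2, 2))
    s2[:, 0, 0] = acc_gdd[:, 0]
    s2[:, 0, 1] = s2[:, 1, 0] = acc_gdd[:, 1]
    s2[:, 1, 1] = acc_gdd[:, 2]

    # dL/d(amplitude) and dL/d(2D mean)
    grad_amp = acc_e
    grad_phat = np.einsum("mij,mj->mi", a_hat, acc_gd)

    # amplitude chain: amp = rho * sqrt(2 pi det_t / det_h)
    c_amp = np.sqrt(2.0 * np.pi * det_t / det_h)
    grad_rho = c_amp * grad_amp
    grad_c = gset.densities * grad_amp
    grad_det_t = grad_c * c_amp / (2.0 * det_t)
    grad_det_h = -grad_c * c_amp / (2.0 * det_h)

    # dL/dSigma_hat: exponent part + det part
    grad_sigma_h = 0.5 * np.einsum("mij,mjk,mkl->mil", a_hat, s2, a_hat)
    grad_sigma_h += grad_det_h[:, None, None] * det_h[:, None, None] * a_hat
    # dL/dSigma_tilde: embedded 2x2 block + det part
    inv_t = np.linalg.inv(sigma_t)
    grad_sigma_t = grad_det_t[:, None, None] * det_t[:, None, None] * inv_t
    grad_sigma_t[:, :2, :2] += grad_sigma_h

    # Sigma_tilde = K Sigma K^T
    grad_sigma = np.einsum("mji,mjk,mkl->mil", k_mat, grad_sigma_t, k_mat)
    grad_k = 2.0 * np.einsum("mij,mjk,mkl->mil", grad_sigma_t, k_mat, sigma)
    grad_jac = grad_k @ w_mat.T

    # dL/dt from the projected mean (u, v) = f * (t0, t1) / t2
    t0, t1, t2 = t.T
    m_norm = np.linalg.norm(t, axis=1)
    grad_t = np.zeros((m, 3))
    grad_t[:, 0] += grad_phat[:, 0] * f / t2
    grad_t[:, 2] += grad_phat[:, 0] * (-f * t0 / t2**2)
    grad_t[:, 1] += grad_phat[:, 1] * f / t2
    grad_t[:, 2] += grad_phat[:, 1] * (-f * t1 / t2**2)
    # dL/dt from J's dependence on t
    grad_t[:, 2] += grad_jac[:, 0, 0] * (-f / t2**2)
    grad_t[:, 0] += grad_jac[:, 0, 2] * (-f / t2**2)
    grad_t[:, 2] += grad_jac[:, 0, 2] * (2.0 * f * t0 / t2**3)
    grad_t[:, 2] += grad_jac[:, 1, 1] * (-f / t2**2)
    grad_t[:, 1] += grad_jac[:, 1, 2] * (-f / t2**2)
    grad_t[:, 2] += grad_jac[:, 1, 2] * (2.0 * f * t1 / t2**3)
    for a in range(3):
        ta = t[:, a]
        for b in range(3):
            tb = t[:, b]
            d = (1.0 if a == b else 0.0) / m_norm - ta * tb / m_norm**3
            grad_t[:, b] += grad_jac[:, 2, a] * d

    grad_pos = grad_t @ w_mat
    grad_s, grad_q = cov_grad_to_params(
        gset, 0.5 * (grad_sigma + grad_sigma.transpose(0, 2, 1))
    )
    off = ~valid
    grad_pos[off] = 0.0
    grad_rho[off] = 0.0
    grad_s[off] = 0.0
    grad_q[off] = 0.0
    return {
        "positions": grad_pos, "densities": grad_rho,
        "scales": grad_s, "quaternions": grad_q,
    }
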