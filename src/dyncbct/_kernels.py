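"""Numba kernels: ray integration, backprojection, warping, Gaussian evaluation.

Every forward kernel that participates in optimization has a matching
backward/adjoint kernel that traverses the data in exactly the same order and
with exactly the same interpolation weights, so the discrete adjoint identity
holds to rounding error and hand-assembled gradients are exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# trilinear helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _clamp_index(f, n):
    # edge-clamped continuous index; returns (i0, frac, inside_derivative)
    if f <= 0.0:
        return 0, 0.0, 0.0
    if f >= n - 1:
        return n - 2, 1.0, 0.0
    i0 = int(f)
    if i0 > n - 2:
        i0 = n - 2
    return i0, f - i0, 1.0


@njit(cache=True)
def _trilinear(vol, fx, fy, fz):
    nx, ny, nz = vol.shape
    ix, ax, _ = _clamp_index(fx, nx)
    iy, ay, _ = _clamp_index(fy, ny)
    iz, az, _ = _clamp_index(fz, nz)
    c000 = vol[ix, iy, iz]
    c100 = vol[ix + 1, iy, iz]
    c010 = vol[ix, iy + 1, iz]
    c110 = vol[ix + 1, iy + 1, iz]
    c001 = vol[ix, iy, iz + 1]
    c101 = vol[ix + 1, iy, iz + 1]
    c011 = vol[ix, iy + 1, iz + 1]
    c111 = vol[ix + 1, iy + 1, iz + 1]
    c00 = c000 * (1 - ax) + c100 * ax
    c10 = c010 * (1 - ax) + c110 * ax
    c01 = c001 * (1 - ax) + c101 * ax
    c11 = c011 * (1 - ax) + c111 * ax
    c0 = c00 * (1 - ay) + c10 * ay
    c1 = c01 * (1 - ay) + c11 * ay
    return c0 * (1 - az) + c1 * az


# ---------------------------------------------------------------------------
# ray-driven line integration (Joseph-style stepping with trilinear samples)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _ray_box(px, py, pz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    tn = -1.0e30
    tf = 1.0e30
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = px, dx, lo0, hi0
        elif axis == 1:
            p, d, lo, hi = py, dy, lo1, hi1
        else:
            p, d, lo, hi = pz, dz, lo2, hi2
        if abs(d) < 1.0e-12:
            if p < lo or p > hi:
                return 1.0, 0.0
        else:
            t1 = (lo - p) / d
            t2 = (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tn:
                tn = t1
            if t2 < tf:
                tf = t2
    return tn, tf


@njit(cache=True, fastmath=True)
def joseph_forward(vol, origin, spacing, src, pix00, du_vec, dv_vec, step, out):
    nx, ny, nz = vol.shape
    lo0 = origin[0] - 0.5 * spacing[0]
    lo1 = origin[1] - 0.5 * spacing[1]
    lo2 = origin[2] - 0.5 * spacing[2]
    hi0 = origin[0] + (nx - 0.5) * spacing[0]
    hi1 = origin[1] + (ny - 0.5) * spacing[1]
    hi2 = origin[2] + (nz - 0.5) * spacing[2]
    n_v, n_u = out.shape
    for iv in range(n_v):
        for iu in range(n_u):
            tx = pix00[0] + iu * du_vec[0] + iv * dv_vec[0] - src[0]
            ty = pix00[1] + iu * du_vec[1] + iv * dv_vec[1] - src[1]
            tz = pix00[2] + iu * du_vec[2] + iv * dv_vec[2] - src[2]
            norm = np.sqrt(tx * tx + ty * ty + tz * tz)
            dx, dy, dz = tx / norm, ty / norm, tz / norm
            tn, tf = _ray_box(src[0], src[1], src[2], dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2)
            if tf <= tn:
                out[iv, iu] = 0.0
                continue
            nsteps = int(np.ceil((tf - tn) / step))
            h = (tf - tn) / nsteps
            acc = 0.0
            for j in range(nsteps):
                t = tn + (j + 0.5) * h
                fx = (src[0] + t * dx - origin[0]) / spacing[0]
                fy = (src[1] + t * dy - origin[1]) / spacing[1]
                fz = (src[2] + t * dz - origin[2]) / spacing[2]
                acc += _trilinear(vol, fx, fy, fz)
            out[iv, iu] = acc * h


@njit(cache=True, fastmath=True)
def joseph_adjoint(grad_frame, origin, spacing, src, pix00, du_vec, dv_vec, step, grad_vol):
    nx, ny, nz = grad_vol.shape
    lo0 = origin[0] - 0.5 * spacing[0]
    lo1 = origin[1] - 0.5 * spacing[1]
    lo2 = origin[2] - 0.5 * spacing[2]
    hi0 = origin[0] + (nx - 0.5) * spacing[0]
    hi1 = origin[1] + (ny - 0.5) * spacing[1]
    hi2 = origin[2] + (nz - 0.5) * spacing[2]
    n_v, n_u = grad_frame.shape
    for iv in range(n_v):
        for iu in range(n_u):
            g = grad_frame[iv, iu]
            if g == 0.0:
                continue
            tx = pix00[0] + iu * du_vec[0] + iv * dv_vec[0] - src[0]
            ty = pix00[1] + iu * du_vec[1] + iv * dv_vec[1] - src[1]
            tz = pix00[2] + iu * du_vec[2] + iv * dv_vec[2] - src[2]
            norm = np.sqrt(tx * tx + ty * ty + tz * tz)
            dx, dy, dz = tx / norm, ty / norm, tz / norm
            tn, tf = _ray_box(src[0], src[1], src[2], dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2)
            if tf <= tn:
                continue
            nsteps = int(np.ceil((tf - tn) / step))
            h = (tf - tn) / nsteps
            gh = g * h
            for j in range(nsteps):
                t = tn + (j + 0.5) * h
                fx = (src[0] + t * dx - origin[0]) / spacing[0]
                fy = (src[1] + t * dy - origin[1]) / spacing[1]
                fz = (src[2] + t * dz - origin[2]) / spacing[2]
                ix, ax, _ = _clamp_index(fx, nx)
                iy, ay, _ = _clamp_index(fy, ny)
                iz, az, _ = _clamp_index(fz, nz)
                grad_vol[ix, iy, iz] += gh * (1 - ax) * (1 - ay) * (1 - az)
                grad_vol[ix + 1, iy, iz] += gh * ax * (1 - ay) * (1 - az)
                grad_vol[ix, iy + 1, iz] += gh * (1 - ax) * ay * (1 - az)
                grad_vol[ix + 1, iy + 1, iz] += gh * ax * ay * (1 - az)
                grad_vol[ix, iy, iz + 1] += gh * (1 - ax) * (1 - ay) * az
                grad_vol[ix + 1, iy, iz + 1] += gh * ax * (1 - ay) * az
                grad_vol[ix, iy + 1, iz + 1] += gh * (1 - ax) * ay * az
                grad_vol[ix + 1, iy + 1, iz + 1] += gh * ax * ay * az


# ---------------------------------------------------------------------------
# FDK voxel-driven backprojection
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def fdk_backproject(frames, srcs, rows, sad, sdd, u0, du, v0, dv, view_weights,
                    origin, spacing, out):
    """Accumulate weighted filtered frames into ``out``.

    ``frames`` are filtered projections on the physical detector; detector
    pixel (iu, iv) sits at (u0 + iu*du, v0 + iv*dv) mm from the piercing
    point.  ``rows[k]`` holds the view matrix rows (u axis, v axis, beam).
    """
    n_views = frames.shape[0]
    n_v, n_u = frames.shape[1], frames.shape[2]
    nx, ny, nz = out.shape
    for k in range(n_views):
        sx, sy, sz = srcs[k, 0], srcs[k, 1], srcs[k, 2]
        ux, uy, uz = rows[k, 0, 0], rows[k, 0, 1], rows[k, 0, 2]
        vx, vy, vz = rows[k, 1, 0], rows[k, 1, 1], rows[k, 1, 2]
        bx, by, bz = rows[k, 2, 0], rows[k, 2, 1], rows[k, 2, 2]
        wk = view_weights[k]
        for i in range(nx):
            x = origin[0] + i * spacing[0]
            for j in range(ny):
                y = origin[1] + j * spacing[1]
                for l in range(nz):
                    z = origin[2] + l * spacing[2]
                    rx, ry, rz = x - sx, y - sy, z - sz
                    t2 = rx * bx + ry * by + rz * bz
                    if t2 <= 1.0:
                        continue
                    t0 = rx * ux + ry * uy + rz * uz
                    t1 = rx * vx + ry * vy + rz * vz
                    u = sdd * t0 / t2
                    v = sdd * t1 / t2
                    fu = (u - u0) / du
                    fv = (v - v0) / dv
                    if fu < 0.0 or fu > n_u - 1 or fv < 0.0 or fv > n_v - 1:
                        continue
                    iu = int(fu)
                    if iu > n_u - 2:
                        iu = n_u - 2
                    iv = int(fv)
                    if iv > n_v - 2:
                        iv = n_v - 2
                    au = fu - iu
                    av = fv - iv
                    val = (
                        frames[k, iv, iu] * (1 - au) * (1 - av)
                        + frames[k, iv, iu + 1] * au * (1 - av)
                        + frames[k, iv + 1, iu] * (1 - au) * av
                        + frames[k, iv + 1, iu + 1] * au * av
                    )
                    out[i, j, l] += wk * val * (sad / t2) ** 2


# ---------------------------------------------------------------------------
# backward warping (pull) with edge clamp
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def warp_forward(ref, vec, origin, spacing, out):
    nx, ny, nz = ref.shape
    for i in range(nx):
        for j in range(ny):
            for l in range(nz):
                fx = (origin[0] + i * spacing[0] + vec[i, j, l, 0] - origin[0]) / spacing[0]
                fy = (origin[1] + j * spacing[1] + vec[i, j, l, 1] - origin[1]) / spacing[1]
                fz = (origin[2] + l * spacing[2] + vec[i, j, l, 2] - origin[2]) / spacing[2]
                out[i, j, l] = _trilinear(ref, fx, fy, fz)


@njit(cache=True, fastmath=True)
def warp_backward(ref, vec, origin, spacing, grad_out, grad_ref, grad_vec):
    """Gradients of warp_forward w.r.t. the reference values and the DVF."""
    nx, ny, nz = ref.shape
    for i in range(nx):
        for j in range(ny):
            for l in range(nz):
                g = grad_out[i, j, l]
                fx = i + vec[i, j, l, 0] / spacing[0]
                fy = j + vec[i, j, l, 1] / spacing[1]
                fz = l + vec[i, j, l, 2] / spacing[2]
                ix, ax, mx = _clamp_index(fx, nx)
                iy, ay, my = _clamp_index(fy, ny)
                iz, az, mz = _clamp_index(fz, nz)
                if g != 0.0:
                    grad_ref[ix, iy, iz] += g * (1 - ax) * (1 - ay) * (1 - az)
                    grad_ref[ix + 1, iy, iz] += g * ax * (1 - ay) * (1 - az)
                    grad_ref[ix, iy + 1, iz] += g * (1 - ax) * ay * (1 - az)
                    grad_ref[ix + 1, iy + 1, iz] += g * ax * ay * (1 - az)
                    grad_ref[ix, iy, iz + 1] += g * (1 - ax) * (1 - ay) * az
                    grad_ref[ix + 1, iy, iz + 1] += g * ax * (1 - ay) * az
                    grad_ref[ix, iy + 1, iz + 1] += g * (1 - ax) * ay * az
                    grad_ref[ix + 1, iy + 1, iz + 1] += g * ax * ay * az
                    c000 = ref[ix, iy, iz]
                    c100 = ref[ix + 1, iy, iz]
                    c010 = ref[ix, iy + 1, iz]
                    c110 = ref[ix + 1, iy + 1, iz]
                    c001 = ref[ix, iy, iz + 1]
                    c101 = ref[ix + 1, iy, iz + 1]
                    c011 = ref[ix, iy + 1, iz + 1]
                    c111 = ref[ix + 1, iy + 1, iz + 1]
                    # d(sample)/d(frac) per axis
                    dx = ((c100 - c000) * (1 - ay) + (c110 - c010) * ay) * (1 - az) + (
                        (c101 - c001) * (1 - ay) + (c111 - c011) * ay
                    ) * az
                    dy = ((c010 - c000) * (1 - ax) + (c110 - c100) * ax) * (1 - az) + (
                        (c011 - c001) * (1 - ax) + (c111 - c101) * ax
                    ) * az
                    dz = ((c001 - c000) * (1 - ax) + (c101 - c100) * ax) * (1 - ay) + (
                        (c011 - c010) * (1 - ax) + (c111 - c110) * ax
                    ) * ay
                    grad_vec[i, j, l, 0] += g * dx * mx / spacing[0]
                    grad_vec[i, j, l, 1] += g * dy * my / spacing[1]
                    grad_vec[i, j, l, 2] += g * dz * mz / spacing[2]


# ---------------------------------------------------------------------------
# grid-to-grid trilinear resampling (MBC basis upsampling) and its adjoint
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def resample_forward(src, src_origin, src_spacing, dst_origin, dst_spacing, out):
    nx, ny, nz = out.shape
    for i in range(nx):
        fx = (dst_origin[0] + i * dst_spacing[0] - src_origin[0]) / src_spacing[0]
        for j in range(ny):
            fy = (dst_origin[1] + j * dst_spacing[1] - src_origin[1]) / src_spacing[1]
            for l in range(nz):
                fz = (dst_origin[2] + l * dst_spacing[2] - src_origin[2]) / src_spacing[2]
                out[i, j, l] = _trilinear(src, fx, fy, fz)


@njit(cache=True, fastmath=True)
def resample_adjoint(grad_dst, src_shape0, src_shape1, src_shape2,
                     src_origin, src_spacing, dst_origin, dst_spacing, grad_src):
    nx, ny, nz = grad_dst.shape
    for i in range(nx):
        fx = (dst_origin[0] + i * dst_spacing[0] - src_origin[0]) / src_spacing[0]
        for j in range(ny):
            fy = (dst_origin[1] + j * dst_spacing[1] - src_origin[1]) / src_spacing[1]
            for l in range(nz):
                g = grad_dst[i, j, l]
                if g == 0.0:
                    continue
                fz = (dst_origin[2] + l * dst_spacing[2] - src_origin[2]) / src_spacing[2]
                ix, ax, _ = _clamp_index(fx, src_shape0)
                iy, ay, _ = _clamp_index(fy, src_shape1)
                iz, az, _ = _clamp_index(fz, src_shape2)
                grad_src[ix, iy, iz] += g * (1 - ax) * (1 - ay) * (1 - az)
                grad_src[ix + 1, iy, iz] += g * ax * (1 - ay) * (1 - az)
                grad_src[ix, iy + 1, iz] += g * (1 - ax) * ay * (1 - az)
                grad_src[ix + 1, iy + 1, iz] += g * ax * ay * (1 - az)
                grad_src[ix, iy, iz + 1] += g * (1 - ax) * (1 - ay) * az
                grad_src[ix + 1, iy, iz + 1] += g * ax * (1 - ay) * az
                grad_src[ix, iy + 1, iz + 1] += g * (1 - ax) * ay * az
                grad_src[ix + 1, iy + 1, iz + 1] += g * ax * ay * az


# ---------------------------------------------------------------------------
# Gaussian voxelization (3-sigma truncated) forward and backward
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def voxelize_fwd(pos, rho, inv_cov, half_extent, origin, spacing, out, qmax):
    """Accumulate sum_i rho_i exp(-q_i/2) at voxel centers; q truncated at qmax."""
    nx, ny, nz = out.shape
    m = pos.shape[0]
    for k in range(m):
        if rho[k] == 0.0:
            continue
        x0 = int(np.ceil((pos[k, 0] - half_extent[k, 0] - origin[0]) / spacing[0]))
        x1 = int(np.floor((pos[k, 0] + half_extent[k, 0] - origin[0]) / spacing[0]))
        y0 = int(np.ceil((pos[k, 1] - half_extent[k, 1] - origin[1]) / spacing[1]))
        y1 = int(np.floor((pos[k, 1] + half_extent[k, 1] - origin[1]) / spacing[1]))
        z0 = int(np.ceil((pos[k, 2] - half_extent[k, 2] - origin[2]) / spacing[2]))
        z1 = int(np.floor((pos[k, 2] + half_extent[k, 2] - origin[2]) / spacing[2]))
        if x0 < 0:
            x0 = 0
        if y0 < 0:
            y0 = 0
        if z0 < 0:
            z0 = 0
        if x1 > nx - 1:
            x1 = nx - 1
        if y1 > ny - 1:
            y1 = ny - 1
        if z1 > nz - 1:
            z1 = nz - 1
        a00 = inv_cov[k, 0, 0]
        a01 = inv_cov[k, 0, 1]
        a02 = inv_cov[k, 0, 2]
        a11 = inv_cov[k, 1, 1]
        a12 = inv_cov[k, 1, 2]
        a22 = inv_cov[k, 2, 2]
        for i in range(x0, x1 + 1):
            dx = origin[0] + i * spacing[0] - pos[k, 0]
            for j in range(y0, y1 + 1):
                dy = origin[1] + j * spacing[1] - pos[k, 1]
                for l in range(z0, z1 + 1):
                    dz = origin[2] + l * spacing[2] - pos[k, 2]
                    q = (
                        a00 * dx * dx + a11 * dy * dy + a22 * dz * dz
                        + 2.0 * (a01 * dx * dy + a02 * dx * dz + a12 * dy * dz)
                    )
                    if q <= qmax:
                        out[i, j, l] += rho[k] * np.exp(-0.5 * q)


@njit(cache=True, fastmath=True)
def voxelize_bwd(pos, rho, inv_cov, half_extent, origin, spacing, grad_vol,
                 acc_e, acc_gd, acc_gdd, qmax):
    """Per-kernel sums needed to assemble parameter gradients.

    acc_e[k]   = sum_vox g * exp(-q/2)
    acc_gd[k]  = sum_vox g * val * delta          (val = rho * exp(-q/2))
    acc_gdd[k] = sum_vox g * val * delta delta^T  (upper triangle, 6 entries)
    """
    nx, ny, nz = grad_vol.shape
    m = pos.shape[0]
    for k in range(m):
        x0 = int(np.ceil((pos[k, 0] - half_extent[k, 0] - origin[0]) / spacing[0]))
        x1 = int(np.floor((pos[k, 0] + half_extent[k, 0] - origin[0]) / spacing[0]))
        y0 = int(np.ceil((pos[k, 1] - half_extent[k, 1] - origin[1]) / spacing[1]))
        y1 = int(np.floor((pos[k, 1] + half_extent[k, 1] - origin[1]) / spacing[1]))
        z0 = int(np.ceil((pos[k, 2] - half_extent[k, 2] - origin[2]) / spacing[2]))
        z1 = int(np.floor((pos[k, 2] + half_extent[k, 2] - origin[2]) / spacing[2]))
        if x0 < 0:
            x0 = 0
        if y0 < 0:
            y0 = 0
        if z0 < 0:
            z0 = 0
        if x1 > nx - 1:
            x1 = nx - 1
        if y1 > ny - 1:
            y1 = ny - 1
        if z1 > nz - 1:
            z1 = nz - 1
        a00 = inv_cov[k, 0, 0]
        a01 = inv_cov[k, 0, 1]
        a02 = inv_cov[k, 0, 2]
        a11 = inv_cov[k, 1, 1]
        a12 = inv_cov[k, 1, 2]
        a22 = inv_cov[k, 2, 2]
        for i in range(x0, x1 + 1):
            dx = origin[0] + i * spacing[0] - pos[k, 0]
            for j in range(y0, y1 + 1):
                dy = origin[1] + j * spacing[1] - pos[k, 1]
                for l in range(z0, z1 + 1):
                    g = grad_vol[i, j, l]
                    if g == 0.0:
                        continue
                    dz = origin[2] + l * spacing[2] - pos[k, 2]
                    q = (
                        a00 * dx * dx + a11 * dy * dy + a22 * dz * dz
                        + 2.0 * (a01 * dx * dy + a02 * dx * dz + a12 * dy * dz)
                    )
                    if q <= qmax:
                        e = np.exp(-0.5 * q)
                        acc_e[k] += g * e
                        gv = g * rho[k] * e
                        acc_gd[k, 0] += gv * dx
                        acc_gd[k, 1] += gv * dy
                        acc_gd[k, 2] += gv * dz
                        acc_gdd[k, 0] += gv * dx * dx
                        acc_gdd[k, 1] += gv * dy * dy
                        acc_gdd[k, 2] += gv * dz * dz
                        acc_gdd[k, 3] += gv * dx * dy
                        acc_gdd[k, 4] += gv * dx * dz
                        acc_gdd[k, 5] += gv * dy * dz


# ---------------------------------------------------------------------------
# 2D splat rasterization (detector-plane Gaussians) forward and backward
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def splat_fwd(phat, inv_cov2, rhohat, half_extent, u0, du, v0, dv, out, qmax):
    n_v, n_u = out.shape
    m = phat.shape[0]
    for k in range(m):
        if rhohat[k] == 0.0:
            continue
        iu0 = int(np.ceil((phat[k, 0] - half_extent[k, 0] - u0) / du))
        iu1 = int(np.floor((phat[k, 0] + half_extent[k, 0] - u0) / du))
        iv0 = int(np.ceil((phat[k, 1] - half_extent[k, 1] - v0) / dv))
        iv1 = int(np.floor((phat[k, 1] + half_extent[k, 1] - v0) / dv))
        if iu0 < 0:
            iu0 = 0
        if iv0 < 0:
            iv0 = 0
        if iu1 > n_u - 1:
            iu1 = n_u - 1
        if iv1 > n_v - 1:
            iv1 = n_v - 1
        a = inv_cov2[k, 0]
        b = inv_cov2[k, 1]
        c = inv_cov2[k, 2]
        for iv in range(iv0, iv1 + 1):
            dyy = v0 + iv * dv - phat[k, 1]
            for iu in range(iu0, iu1 + 1):
                dxx = u0 + iu * du - phat[k, 0]
                q = a * dxx * dxx + 2.0 * b * dxx * dyy + c * dyy * dyy
                if q <= qmax:
                    out[iv, iu] += rhohat[k] * np.exp(-0.5 * q)


@njit(cache=True, fastmath=True)
def splat_bwd(phat, inv_cov2, rhohat, half_extent, u0, du, v0, dv, grad_img,
              acc_e, acc_gd, acc_gdd, qmax):
    n_v, n_u = grad_img.shape
    m = phat.shape[0]
    for k in range(m):
        iu0 = int(np.ceil((phat[k, 0] - half_extent[k, 0] - u0) / du))
        iu1 = int(np.floor((phat[k, 0] + half_extent[k, 0] - u0) / du))
        iv0 = int(np.ceil((phat[k, 1] - half_extent[k, 1] - v0) / dv))
        iv1 = int(np.floor((phat[k, 1] + half_extent[k, 1] - v0) / dv))
        if iu0 < 0:
            iu0 = 0
        if iv0 < 0:
            iv0 = 0
        if iu1 > n_u - 1:
            iu1 = n_u - 1
        if iv1 > n_v - 1:
            iv1 = n_v - 1
        a = inv_cov2[k, 0]
        b = inv_cov2[k, 1]
        c = inv_cov2[k, 2]
        for iv in range(iv0, iv1 + 1):
            dyy = v0 + iv * dv - phat[k, 1]
            for iu in range(iu0, iu1 + 1):
                g = grad_img[iv, iu]
                if g == 0.0:
                    continue
                dxx = u0 + iu * du - phat[k, 0]
                q = a * dxx * dxx + 2.0 * b * dxx * dyy + c * dyy * dyy
                if q <= qmax:
                    e = np.exp(-0.5 * q)
                    acc_e[k] += g * e
                    gv = g * rhohat[k] * e
                    acc_gd[k, 0] += gv * dxx
                    acc_gd[k, 1] += gv * dyy
                    acc_gdd[k, 0] += gv * dxx * dxx
                    acc_gdd[k, 1] += gv * dxx * dyy
                    acc_gdd[k, 2] += gv * dyy * dyy
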