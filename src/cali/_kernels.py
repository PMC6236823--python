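"""Numba kernels: ray-driven projection and voxel-driven backprojection.

The forward kernel marches each source->pixel ray through the volume at a
fixed step, gathering trilinearly interpolated samples.  Its exact adjoint
(`scatter_backproject`) walks the same rays and scatters detector values into
the volume with the same trilinear weights -- the pair is used by the
iterative TV reconstruction.  `voxel_backproject` is the conventional
FDK-style voxel-driven backprojector with bilinear detector interpolation and
a per-voxel 1/U^2 distance weight option.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_NOPYTHON = dict(cache=True, fastmath=True)


@njit(**_NOPYTHON)
def _ray_box(sx, sy, sz, dx, dy, dz, x0, x1, y0, y1, z0, z1, tfar):
    tmin = 0.0
    tmax = tfar
    for axis in range(3):
        if axis == 0:
            s, d, lo, hi = sx, dx, x0, x1
        elif axis == 1:
            s, d, lo, hi = sy, dy, y0, y1
        else:
            s, d, lo, hi = sz, dz, z0, z1
        if abs(d) < 1e-12:
            if s < lo or s > hi:
                return 1.0, 0.0
        else:
            t1 = (lo - s) / d
            t2 = (hi - s) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(**_NOPYTHON)
def forward_kernel(vol, voxel, ox, oy, oz, sad, sdd, pitch, off_v, off_u,
                   angles_rad, step, out):
    nx, ny, nz = vol.shape
    nviews, nrows, ncols = out.shape
    x0, x1 = ox, ox + nx * voxel
    y0, y1 = oy, oy + ny * voxel
    z0, z1 = oz, oz + nz * voxel
    for iv in range(nviews):
        beta = angles_rad[iv]
        cb = np.cos(beta)
        sb = np.sin(beta)
        sx = sad * cb
        sy = sad * sb
        sz = 0.0
        # detector center
        dcx = sx - sdd * cb
        dcy = sy - sdd * sb
        for r in range(nrows):
            v = (r - (nrows - 1) / 2) * pitch + off_v
            for c in range(ncols):
                u = (c - (ncols - 1) / 2) * pitch + off_u
                px = dcx - u * sb
                py = dcy + u * cb
                pz = v
                dx = px - sx
                dy = py - sy
                dz = pz - sz
                L = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= L
                dy /= L
                dz /= L
                tmin, tmax = _ray_box(sx, sy, sz, dx, dy, dz,
                                      x0, x1, y0, y1, z0, z1, L * 2.0)
                if tmax <= tmin:
                    out[iv, r, c] = 0.0
                    continue
                acc = 0.0
                t = tmin + 0.5 * step
                while t < tmax:
                    gx = (sx + t * dx - ox) / voxel - 0.5
                    gy = (sy + t * dy - oy) / voxel - 0.5
                    gz = (sz + t * dz - oz) / voxel - 0.5
                    ix = int(np.floor(gx))
                    iy = int(np.floor(gy))
                    iz = int(np.floor(gz))
                    fx = gx - ix
                    fy = gy - iy
                    fz = gz - iz
                    # trilinear gather with zero padding outside
                    val = 0.0
                    for a in range(2):
                        xa = ix + a
                        if xa < 0 or xa >= nx:
                            continue
                        wa = fx if a == 1 else 1.0 - fx
                        for b in range(2):
                            yb = iy + b
                            if yb < 0 or yb >= ny:
                                continue
                            wb = fy if b == 1 else 1.0 - fy
                            for g in range(2):
                                zg = iz + g
                                if zg < 0 or zg >= nz:
                                    continue
                                wg = fz if g == 1 else 1.0 - fz
                                val += wa * wb * wg * vol[xa, yb, zg]
                    acc += val
                    t += step
                out[iv, r, c] = acc * step


@njit(**_NOPYTHON)
def scatter_backproject_kernel(proj, voxel, ox, oy, oz, sad, sdd, pitch,
                               off_v, off_u, angles_rad, step, out):
    """Exact adjoint of forward_kernel (scatter with the same weights)."""
    nx, ny, nz = out.shape
    nviews, nrows, ncols = proj.shape
    x0, x1 = ox, ox + nx * voxel
    y0, y1 = oy, oy + ny * voxel
    z0, z1 = oz, oz + nz * voxel
    for iv in range(nviews):
        beta = angles_rad[iv]
        cb = np.cos(beta)
        sb = np.sin(beta)
        sx = sad * cb
        sy = sad * sb
        sz = 0.0
        dcx = sx - sdd * cb
        dcy = sy - sdd * sb
        for r in range(nrows):
            v = (r - (nrows - 1) / 2) * pitch + off_v
            for c in range(ncols):
                val = proj[iv, r, c]
                if val == 0.0:
                    continue
                u = (c - (ncols - 1) / 2) * pitch + off_u
                px = dcx - u * sb
                py = dcy + u * cb
                pz = v
                dx = px - sx
                dy = py - sy
                dz = pz - sz
                L = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= L
                dy /= L
                dz /= L
                tmin, tmax = _ray_box(sx, sy, sz, dx, dy, dz,
                                      x0, x1, y0, y1, z0, z1, L * 2.0)
                if tmax <= tmin:
                    continue
                contrib = val * step
                t = tmin + 0.5 * step
                while t < tmax:
                    gx = (sx + t * dx - ox) / voxel - 0.5
                    gy = (sy + t * dy - oy) / voxel - 0.5
                    gz = (sz + t * dz - oz) / voxel - 0.5
                    ix = int(np.floor(gx))
                    iy = int(np.floor(gy))
                    iz = int(np.floor(gz))
                    fx = gx - ix
                    fy = gy - iy
                    fz = gz - iz
                    for a in range(2):
                        xa = ix + a
                        if xa < 0 or xa >= nx:
                            continue
                        wa = fx if a == 1 else 1.0 - fx
                        for b in range(2):
                            yb = iy + b
                            if yb < 0 or yb >= ny:
                                continue
                            wb = fy if b == 1 else 1.0 - fy
                            for g in range(2):
                                zg = iz + g
                                if zg < 0 or zg >= nz:
                                    continue
                                wg = fz if g == 1 else 1.0 - fz
                                out[xa, yb, zg] += wa * wb * wg * contrib
                    t += step


@njit(**_NOPYTHON)
def voxel_backproject_kernel(proj, angles_rad, sad, pitch_v, pitch_u,
                             off_v, off_u, voxel, ox, oy, oz,
                             distance_weight, out):
    """Voxel-driven backprojection with bilinear detector interpolation.

    ``proj`` must be given on the virtual detector through the isocenter
    (coordinates already scaled by SAD/SDD).  With ``distance_weight`` true
    each view contributes with the FDK SAD^2/U^2 factor, otherwise with unit
    weight (used for the unfiltered energy backprojection).
    """
    nx, ny, nz = out.shape
    nviews, nrows, ncols = proj.shape
    for iv in range(nviews):
        beta = angles_rad[iv]
        cb = np.cos(beta)
        sb = np.sin(beta)
        for i in range(nx):
            x = ox + (i + 0.5) * voxel
            for j in range(ny):
                y = oy + (j + 0.5) * voxel
                t = x * cb + y * sb
                s = -x * sb + y * cb
                U = sad - t
                if U < 1e-6:
                    continue
                mag = sad / U
                ustar = s * mag
                cu = (ustar - off_u) / pitch_u + (ncols - 1) / 2
                if cu < 0.0 or cu > ncols - 1:
                    continue
                ic = int(np.floor(cu))
                if ic >= ncols - 1:
                    ic = ncols - 2
                fu = cu - ic
                w = (sad * sad) / (U * U) if distance_weight else 1.0
                for k in range(nz):
                    z = oz + (k + 0.5) * voxel
                    vstar = z * mag
                    rv = (vstar - off_v) / pitch_v + (nrows - 1) / 2
                    if rv < 0.0 or rv > nrows - 1:
                        continue
                    ir = int(np.floor(rv))
                    if ir >= nrows - 1:
                        ir = nrows - 2
                    fv = rv - ir
                    val = ((1 - fv) * ((1 - fu) * proj[iv, ir, ic]
                                       + fu * proj[iv, ir, ic + 1])
                           + fv * ((1 - fu) * proj[iv, ir + 1, ic]
                                   + fu * proj[iv, ir + 1, ic + 1]))
                    out[i, j, k] += w * val
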