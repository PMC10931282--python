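"""Numba kernels: exact Siddon voxel traversal, forward projection and Kaczmarz sweeps.

All kernels operate on a C-contiguous float64 volume indexed ``vol[ix, iy, iz]``
with ``origin`` the world position of the corner of voxel (0, 0, 0) and
``voxel_size`` per-axis spacings in mm.  Rays are straight segments from ``p0``
to ``p1`` in world mm; intersection lengths are exact (Siddon traversal), so the
projector and the ART back-projector share identical weights w_i.
"""

import numpy as np
from numba import njit

# generous upper bound on voxels crossed by one ray
def max_path_len(shape):
    return int(shape[0] + shape[1] + shape[2] + 8)


@njit(cache=True)
def siddon_path(p0x, p0y, p0z, p1x, p1y, p1z,
                ox, oy, oz, vx, vy, vz, nx, ny, nz,
                idx_buf, len_buf):
    """Exact voxel traversal of segment p0→p1. Fills (index, length mm) buffers,
    returns the number of voxels crossed (0 if the ray misses the volume)."""
    dx = p1x - p0x
    dy = p1y - p0y
    dz = p1z - p0z
    L = np.sqrt(dx * dx + dy * dy + dz * dz)
    if L <= 0.0:
        return 0
    tmin = 0.0
    tmax = 1.0
    # slab clipping per axis
    if dx != 0.0:
        t1 = (ox - p0x) / dx
        t2 = (ox + nx * vx - p0x) / dx
        lo = min(t1, t2)
        hi = max(t1, t2)
        if lo > tmin:
            tmin = lo
        if hi < tmax:
            tmax = hi
    else:
        if p0x <= ox or p0x >= ox + nx * vx:
            return 0
    if dy != 0.0:
        t1 = (oy - p0y) / dy
        t2 = (oy + ny * vy - p0y) / dy
        lo = min(t1, t2)
        hi = max(t1, t2)
        if lo > tmin:
            tmin = lo
        if hi < tmax:
            tmax = hi
    else:
        if p0y <= oy or p0y >= oy + ny * vy:
            return 0
    if dz != 0.0:
        t1 = (oz - p0z) / dz
        t2 = (oz + nz * vz - p0z) / dz
        lo = min(t1, t2)
        hi = max(t1, t2)
        if lo > tmin:
            tmin = lo
        if hi < tmax:
            tmax = hi
    else:
        if p0z <= oz or p0z >= oz + nz * vz:
            return 0
    if tmax - tmin <= 1e-12:
        return 0

    # entry voxel
    ex = p0x + tmin * dx
    ey = p0y + tmin * dy
    ez = p0z + tmin * dz
    ix = int(np.floor((ex - ox) / vx))
    iy = int(np.floor((ey - oy) / vy))
    iz = int(np.floor((ez - oz) / vz))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    if iz > nz - 1:
        iz = nz - 1

    big = 1e300
    if dx > 0.0:
        stepx = 1
        tnx = (ox + (ix + 1) * vx - p0x) / dx
        tdx = vx / dx
    elif dx < 0.0:
        stepx = -1
        tnx = (ox + ix * vx - p0x) / dx
        tdx = -vx / dx
    else:
        stepx = 0
        tnx = big
        tdx = big
    if dy > 0.0:
        stepy = 1
        tny = (oy + (iy + 1) * vy - p0y) / dy
        tdy = vy / dy
    elif dy < 0.0:
        stepy = -1
        tny = (oy + iy * vy - p0y) / dy
        tdy = -vy / dy
    else:
        stepy = 0
        tny = big
        tdy = big
    if dz > 0.0:
        stepz = 1
        tnz = (oz + (iz + 1) * vz - p0z) / dz
        tdz = vz / dz
    elif dz < 0.0:
        stepz = -1
        tnz = (oz + iz * vz - p0z) / dz
        tdz = -vz / dz
    else:
        stepz = 0
        tnz = big
        tdz = big

    t = tmin
    count = 0
    while t < tmax - 1e-12:
        tstop = tnx
        if tny < tstop:
            tstop = tny
        if tnz < tstop:
            tstop = tnz
        if tmax < tstop:
            tstop = tmax
        seg = (tstop - t) * L
        if seg > 0.0:
            idx_buf[count, 0] = ix
            idx_buf[count, 1] = iy
            idx_buf[count, 2] = iz
            len_buf[count] = seg
            count += 1
        if tstop >= tmax - 1e-12:
            break
        # advance across the crossed boundary (possibly several at once)
        if tnx <= tstop + 1e-15:
            ix += stepx
            tnx += tdx
        if tny <= tstop + 1e-15:
            iy += stepy
            tny += tdy
        if tnz <= tstop + 1e-15:
            iz += stepz
            tnz += tdz
        t = tstop
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            break
    return count


@njit(cache=True)
def forward_raysums(vol, ox, oy, oz, vx, vy, vz, p0s, p1s, out):
    """Line integrals Σ μ·len for a batch of rays (Beer–Lambert exponents)."""
    nx, ny, nz = vol.shape
    maxlen = nx + ny + nz + 8
    idx_buf = np.empty((maxlen, 3), dtype=np.int64)
    len_buf = np.empty(maxlen, dtype=np.float64)
    n = p0s.shape[0]
    for k in range(n):
        c = siddon_path(p0s[k, 0], p0s[k, 1], p0s[k, 2],
                        p1s[k, 0], p1s[k, 1], p1s[k, 2],
                        ox, oy, oz, vx, vy, vz, nx, ny, nz,
                        idx_buf, len_buf)
        s = 0.0
        for m in range(c):
            s += vol[idx_buf[m, 0], idx_buf[m, 1], idx_buf[m, 2]] * len_buf[m]
        out[k] = s


@njit(cache=True)
def art_sweep(vol, ox, oy, oz, vx, vy, vz, p0s, p1s, pvals, lam):
    """One relaxed Kaczmarz sweep over the given rays, in ray order, with the
    non-negativity projection applied to each updated voxel.  In-place."""
    nx, ny, nz = vol.shape
    maxlen = nx + ny + nz + 8
    idx_buf = np.empty((maxlen, 3), dtype=np.int64)
    len_buf = np.empty(maxlen, dtype=np.float64)
    n = p0s.shape[0]
    for k in range(n):
        c = siddon_path(p0s[k, 0], p0s[k, 1], p0s[k, 2],
                        p1s[k, 0], p1s[k, 1], p1s[k, 2],
                        ox, oy, oz, vx, vy, vz, nx, ny, nz,
                        idx_buf, len_buf)
        if c == 0:
            continue
        s = 0.0
        w2 = 0.0
        for m in range(c):
            w = len_buf[m]
            s += vol[idx_buf[m, 0], idx_buf[m, 1], idx_buf[m, 2]] * w
            w2 += w * w
        if w2 <= 0.0:
            continue
        corr = lam * (pvals[k] - s) / w2
        for m in range(c):
            i0 = idx_buf[m, 0]
            i1 = idx_buf[m, 1]
            i2 = idx_buf[m, 2]
            v = vol[i0, i1, i2] + corr * len_buf[m]
            if v < 0.0:
                v = 0.0
            vol[i0, i1, i2] = v


@njit(cache=True)
def mark_support(mask, ox, oy, oz, vx, vy, vz, p0s, p1s):
    """Set mask voxels crossed by at least one ray (reconstruction support)."""
    nx, ny, nz = mask.shape
    maxlen = nx + ny + nz + 8
    idx_buf = np.empty((maxlen, 3), dtype=np.int64)
    len_buf = np.empty(maxlen, dtype=np.float64)
    n = p0s.shape[0]
    for k in range(n):
        c = siddon_path(p0s[k, 0], p0s[k, 1], p0s[k, 2],
                        p1s[k, 0], p1s[k, 1], p1s[k, 2],
                        ox, oy, oz, vx, vy, vz, nx, ny, nz,
                        idx_buf, len_buf)
        for m in range(c):
            mask[idx_buf[m, 0], idx_buf[m, 1], idx_buf[m, 2]] = True
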