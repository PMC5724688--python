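"""Numba kernels for forward ray tracing through a periodic canopy plot.

Geometry lives in a single plot cell [0,Lx) x [0,Ly) that is tiled
periodically in x and y (an extended-field boundary condition).  Triangles
are binned into a 2D uniform grid over the cell; each grid entry stores the
triangle index plus the image offset (in cell lengths) that makes that
triangle image overlap the cell.  Rays walk cells with a 2D DDA; on leaving
the cell laterally the ray is translated by one cell length (periodic wrap).

Energy handling: each facet hit deterministically splits ray energy into
absorbed / reflected / transmitted per the facet's optics; the scattered
parts continue as cosine-sampled (Lambertian) rays up to ``max_bounces``,
below an absolute energy cutoff the remainder is tallied as ``lost`` so the
energy audit (leaf + soil + escaped + lost = injected) is exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LCG_MULT = np.uint64(6364136223846793005)
_LCG_ADD = np.uint64(1442695040888963407)


@njit(cache=True)
def _rand(state):
    state = state * _LCG_MULT + _LCG_ADD
    return state, np.float64(state >> np.uint64(40)) / 16777216.0


@njit(cache=True)
def _moller_trumbore(ox, oy, oz, dx, dy, dz,
                     ax, ay, az, bx, by, bz, cx, cy, cz, tmin):
    e1x, e1y, e1z = bx - ax, by - ay, bz - az
    e2x, e2y, e2z = cx - ax, cy - ay, cz - az
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-14 < det < 1e-14:
        return -1.0
    inv = 1.0 / det
    tx, ty, tz = ox - ax, oy - ay, oz - az
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= tmin:
        return -1.0
    return t


@njit(cache=True)
def _nearest_hit(ox, oy, oz, dx, dy, dz,
                 v0, v1, v2,
                 cell_start, cell_tri, cell_offx, cell_offy,
                 lx, ly, gx, gy, z_top, tmin):
    """Nearest event along a ray.  Returns (kind, facet, px, py, pz).

    kind: 0 leaf facet, 1 ground (z=0), 2 escaped above z_top, 3 lost.
    """
    ox = ox % lx
    oy = oy % ly
    csx = lx / gx
    csy = ly / gy
    big = 1e30
    for _wrap in range(20000):
        ix = int(ox / csx)
        if ix >= gx:
            ix = gx - 1
        iy = int(oy / csy)
        if iy >= gy:
            iy = gy - 1
        if dx > 0.0:
            t_max_x = ((ix + 1) * csx - ox) / dx
            t_dx = csx / dx
            sx = 1
        elif dx < 0.0:
            t_max_x = (ix * csx - ox) / dx
            t_dx = -csx / dx
            sx = -1
        else:
            t_max_x = big
            t_dx = big
            sx = 0
        if dy > 0.0:
            t_max_y = ((iy + 1) * csy - oy) / dy
            t_dy = csy / dy
            sy = 1
        elif dy < 0.0:
            t_max_y = (iy * csy - oy) / dy
            t_dy = -csy / dy
            sy = -1
        else:
            t_max_y = big
            t_dy = big
            sy = 0

        t_ground = big
        if dz < 0.0:
            t_ground = (0.0 - oz) / dz
        t_top = big
        if dz > 0.0 and oz < z_top:
            t_top = (z_top - oz) / dz
        elif dz > 0.0:
            return 2, -1, ox, oy, oz

        wrapped = False
        while True:
            t_exit = t_max_x if t_max_x < t_max_y else t_max_y
            c = iy * gx + ix
            best_t = big
            best_f = -1
            for e in range(cell_start[c], cell_start[c + 1]):
                f = cell_tri[e]
                sx_off = cell_offx[e] * lx
                sy_off = cell_offy[e] * ly
                t = _moller_trumbore(
                    ox - sx_off, oy - sy_off, oz, dx, dy, dz,
                    v0[f, 0], v0[f, 1], v0[f, 2],
                    v1[f, 0], v1[f, 1], v1[f, 2],
                    v2[f, 0], v2[f, 1], v2[f, 2], tmin,
                )
                if 0.0 < t < best_t:
                    best_t = t
                    best_f = f
            limit = t_exit + 1e-9
            ev = best_t
            if t_ground < ev:
                ev = t_ground
            if t_top < ev:
                ev = t_top
            if ev <= limit:
                if best_t <= ev:
                    return 0, best_f, ox + dx * best_t, oy + dy * best_t, oz + dz * best_t
                if t_ground <= t_top:
                    return 1, -1, (ox + dx * t_ground) % lx, (oy + dy * t_ground) % ly, 0.0
                return 2, -1, ox, oy, oz
            # advance to the next cell
            if t_max_x < t_max_y:
                t_cross = t_max_x
                ix += sx
                t_max_x += t_dx
                out = ix < 0 or ix >= gx
            else:
                t_cross = t_max_y
                iy += sy
                t_max_y += t_dy
                out = iy < 0 or iy >= gy
            if out:
                step = t_cross + 1e-9
                ox = (ox + dx * step) % lx
                oy = (oy + dy * step) % ly
                oz = oz + dz * step
                wrapped = True
                break
        if not wrapped:
            break
    return 3, -1, ox, oy, oz


@njit(cache=True)
def _cosine_dir(nx, ny, nz, u1, u2):
    """Cosine-weighted direction about the (unit) normal."""
    if abs(nz) < 0.9:
        hx, hy, hz = 0.0, 0.0, 1.0
    else:
        hx, hy, hz = 1.0, 0.0, 0.0
    t1x = ny * hz - nz * hy
    t1y = nz * hx - nx * hz
    t1z = nx * hy - ny * hx
    norm = (t1x * t1x + t1y * t1y + t1z * t1z) ** 0.5
    t1x, t1y, t1z = t1x / norm, t1y / norm, t1z / norm
    t2x = ny * t1z - nz * t1y
    t2y = nz * t1x - nx * t1z
    t2z = nx * t1y - ny * t1x
    r = u1 ** 0.5
    phi = 6.283185307179586 * u2
    a = r * np.cos(phi)
    b = r * np.sin(phi)
    c = (1.0 - u1) ** 0.5
    return (a * t1x + b * t2x + c * nx,
            a * t1y + b * t2y + c * ny,
            a * t1z + b * t2z + c * nz)


@njit(cache=True)
def trace_rays(origins, dirs, weights,
               v0, v1, v2, normals, refl, trans,
               cell_start, cell_tri, cell_offx, cell_offy,
               lx, ly, gx, gy, z_top,
               max_bounces, cutoff, soil_refl, seed):
    """Trace primary rays with deterministic energy splitting at each hit.

    Returns (incident_energy, absorbed_energy, soil, escaped, lost); the
    per-facet arrays are energies (weight units), not fluxes.
    """
    n_f = refl.shape[0]
    incident = np.zeros(n_f)
    absorbed = np.zeros(n_f)
    soil = 0.0
    escaped = 0.0
    lost = 0.0
    cap = 2 ** (max_bounces + 2) + 8
    s_o = np.empty((cap, 3))
    s_d = np.empty((cap, 3))
    s_w = np.empty(cap)
    s_depth = np.empty(cap, dtype=np.int64)
    state = np.uint64(seed) * _LCG_MULT + _LCG_ADD
    tmin = 1e-7
    for i in range(weights.shape[0]):
        state = (state + np.uint64(i)) * _LCG_MULT + _LCG_ADD
        top = 0
        s_o[top, 0] = origins[i, 0]
        s_o[top, 1] = origins[i, 1]
        s_o[top, 2] = origins[i, 2]
        s_d[top, 0] = dirs[i, 0]
        s_d[top, 1] = dirs[i, 1]
        s_d[top, 2] = dirs[i, 2]
        s_w[top] = weights[i]
        s_depth[top] = 0
        top += 1
        while top > 0:
            top -= 1
            ox, oy, oz = s_o[top, 0], s_o[top, 1], s_o[top, 2]
            dx, dy, dz = s_d[top, 0], s_d[top, 1], s_d[top, 2]
            w = s_w[top]
            depth = s_depth[top]
            kind, f, px, py, pz = _nearest_hit(
                ox, oy, oz, dx, dy, dz, v0, v1, v2,
                cell_start, cell_tri, cell_offx, cell_offy,
                lx, ly, gx, gy, z_top, tmin,
            )
            if kind == 2:
                escaped += w
            elif kind == 3:
                lost += w
            elif kind == 1:
                w_up = w * soil_refl
                if soil_refl > 0.0 and depth < max_bounces and w_up >= cutoff:
                    soil += w - w_up
                    state, u1 = _rand(state)
                    state, u2 = _rand(state)
                    ddx, ddy, ddz = _cosine_dir(0.0, 0.0, 1.0, u1, u2)
                    s_o[top, 0] = px + ddx * 1e-6
                    s_o[top, 1] = py + ddy * 1e-6
                    s_o[top, 2] = 1e-6
                    s_d[top, 0] = ddx
                    s_d[top, 1] = ddy
                    s_d[top, 2] = ddz
                    s_w[top] = w_up
                    s_depth[top] = depth + 1
                    top += 1
                else:
                    soil += w
            else:
                incident[f] += w
                a = 1.0 - refl[f] - trans[f]
                absorbed[f] += w * a
                w_r = w * refl[f]
                w_t = w * trans[f]
                if depth >= max_bounces:
                    lost += w_r + w_t
                    continue
                nx, ny, nz = normals[f, 0], normals[f, 1], normals[f, 2]
                if dx * nx + dy * ny + dz * nz > 0.0:
                    nx, ny, nz = -nx, -ny, -nz
                if w_r >= cutoff:
                    state, u1 = _rand(state)
                    state, u2 = _rand(state)
                    ddx, ddy, ddz = _cosine_dir(nx, ny, nz, u1, u2)
                    s_o[top, 0] = px + ddx * 1e-6
                    s_o[top, 1] = py + ddy * 1e-6
                    s_o[top, 2] = pz + ddz * 1e-6
                    s_d[top, 0] = ddx
                    s_d[top, 1] = ddy
                    s_d[top, 2] = ddz
                    s_w[top] = w_r
                    s_depth[top] = depth + 1
                    top += 1
                else:
                    lost += w_r
                if w_t >= cutoff:
                    state, u1 = _rand(state)
                    state, u2 = _rand(state)
                    ddx, ddy, ddz = _cosine_dir(-nx, -ny, -nz, u1, u2)
                    s_o[top, 0] = px + ddx * 1e-6
                    s_o[top, 1] = py + ddy * 1e-6
                    s_o[top, 2] = pz + ddz * 1e-6
                    s_d[top, 0] = ddx
                    s_d[top, 1] = ddy
                    s_d[top, 2] = ddz
                    s_w[top] = w_t
                    s_depth[top] = depth + 1
                    top += 1
                else:
                    lost += w_t
    return incident, absorbed, soil, escaped, lost


def build_grid(vertices, triangles, ground_bounds, gx=None, gy=None):
    """Bin triangle images into a periodic 2D grid over the plot cell.

    Returns (cell_start, cell_tri, cell_offx, cell_offy, gx, gy) in CSR
    layout; offsets are in cell lengths (-1, 0, +1).
    """
    xmin, xmax, ymin, ymax = ground_bounds
    lx, ly = xmax - xmin, ymax - ymin
    n_f = len(triangles)
    if gx is None:
        gx = int(np.clip(np.sqrt(max(n_f, 1) / 6.0), 3, 32))
    if gy is None:
        gy = gx
    csx, csy = lx / gx, ly / gy
    tri_xy = vertices[triangles][:, :, :2] - np.array([xmin, ymin])
    lo = tri_xy.min(axis=1)
    hi = tri_xy.max(axis=1)
    entries = []
    eps = 1e-9
    for off_x in (-1, 0, 1):
        for off_y in (-1, 0, 1):
            shift = np.array([off_x * lx, off_y * ly])
            slo = lo + shift
            shi = hi + shift
            # clip to base cell
            c0x = np.floor((np.maximum(slo[:, 0], 0.0)) / csx).astype(int)
            c1x = np.floor((np.minimum(shi[:, 0], lx - eps)) / csx).astype(int)
            c0y = np.floor((np.maximum(slo[:, 1], 0.0)) / csy).astype(int)
            c1y = np.floor((np.minimum(shi[:, 1], ly - eps)) / csy).astype(int)
            ok = (slo[:, 0] < lx) & (shi[:, 0] > 0.0) & (slo[:, 1] < ly) & (shi[:, 1] > 0.0)
            for f in np.nonzero(ok)[0]:
                for cx in range(max(c0x[f], 0), min(c1x[f], gx - 1) + 1):
                    for cy in range(max(c0y[f], 0), min(c1y[f], gy - 1) + 1):
                        entries.append((cy * gx + cx, f, off_x, off_y))
    n_cells = gx * gy
    cell_start = np.zeros(n_cells + 1, dtype=np.int64)
    if entries:
        arr = np.array(entries, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        counts = np.bincount(arr[:, 0], minlength=n_cells)
        cell_start[1:] = np.cumsum(counts)
        cell_tri = np.ascontiguousarray(arr[:, 1])
        cell_offx = np.ascontiguousarray(arr[:, 2])
        cell_offy = np.ascontiguousarray(arr[:, 3])
    else:
        cell_tri = np.zeros(0, dtype=np.int64)
        cell_offx = np.zeros(0, dtype=np.int64)
        cell_offy = np.zeros(0, dtype=np.int64)
    return cell_start, cell_tri, cell_offx, cell_offy, gx, gy
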