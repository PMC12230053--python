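"""Numba Monte-Carlo ray-tracing kernel for canopy light transport.

Geometry is a single plant (parallelogram leaf panels + vertical stem
cylinder segments) instanced by translation onto a planting grid; the soil
is a fully absorbing plane at z = 0 and the scene sides are open.  Rays are
launched from a horizontal rectangle per light source above the canopy and
followed through Lambertian reflection / transmission events until absorbed,
escaped, or truncated at the reflection-depth cap.  Every ray ends in exactly
one tally, so energy is conserved to floating-point accuracy.

Primitive search uses an axis-aligned BVH over the plant's panels plus a
per-instance AABB slab test; a brute-force variant is kept as the reference
for contract tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-9
_STACK = 64


# ------------------------------------------------------------------ BVH build


def build_bvh(p0: np.ndarray, e1: np.ndarray, e2: np.ndarray, leaf_size: int = 4):
    """Median-split BVH over parallelograms; returns flat arrays.

    Node i: box [bmin[i], bmax[i]]; interior -> children (left[i], right[i]);
    leaf -> prims prim_idx[start[i] : start[i] + count[i]].
    """
    m = p0.shape[0]
    if m == 0:
        z = np.zeros((1, 3))
        return (
            z,
            z,
            np.full(1, -1, np.int64),
            np.full(1, -1, np.int64),
            np.zeros(1, np.int64),
            np.zeros(1, np.int64),
            np.zeros(0, np.int64),
        )
    corners = np.stack([p0, p0 + e1, p0 + e2, p0 + e1 + e2], axis=1)  # (m,4,3)
    prim_min = corners.min(axis=1)
    prim_max = corners.max(axis=1)
    centroid = 0.5 * (prim_min + prim_max)

    bmin, bmax, left, right, start, count = [], [], [], [], [], []
    order = np.arange(m)

    def add_node():
        bmin.append(None)
        bmax.append(None)
        left.append(-1)
        right.append(-1)
        start.append(0)
        count.append(0)
        return len(bmin) - 1

    stack = [(add_node(), 0, m)]
    while stack:
        node, lo, hi = stack.pop()
        idx = order[lo:hi]
        bmin[node] = prim_min[idx].min(axis=0)
        bmax[node] = prim_max[idx].max(axis=0)
        if hi - lo <= leaf_size:
            start[node] = lo
            count[node] = hi - lo
            continue
        axis = int(np.argmax(bmax[node] - bmin[node]))
        mid = (lo + hi) // 2
        part = np.argsort(centroid[idx, axis], kind="stable")
        order[lo:hi] = idx[part]
        l_child, r_child = add_node(), add_node()
        left[node], right[node] = l_child, r_child
        stack.append((l_child, lo, mid))
        stack.append((r_child, mid, hi))

    return (
        np.asarray(bmin, dtype=np.float64),
        np.asarray(bmax, dtype=np.float64),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(start, dtype=np.int64),
        np.asarray(count, dtype=np.int64),
        order.astype(np.int64),
    )


# ------------------------------------------------------------ device helpers


@njit(cache=True, inline="always")
def _slab_hit(bmin, bmax, ox, oy, oz, ix, iy, iz, t_max):
    t0 = (bmin[0] - ox) * ix
    t1 = (bmax[0] - ox) * ix
    tn = min(t0, t1)
    tf = max(t0, t1)
    t0 = (bmin[1] - oy) * iy
    t1 = (bmax[1] - oy) * iy
    tn = max(tn, min(t0, t1))
    tf = min(tf, max(t0, t1))
    t0 = (bmin[2] - oz) * iz
    t1 = (bmax[2] - oz) * iz
    tn = max(tn, min(t0, t1))
    tf = min(tf, max(t0, t1))
    return tf >= max(tn, 0.0) and tn <= t_max


@njit(cache=True, inline="always")
def _quad_hit(p0, e1, e2, ox, oy, oz, dx, dy, dz, t_max):
    """Moller-Trumbore for a parallelogram (u, v independently in [0,1])."""
    hx = dy * e2[2] - dz * e2[1]
    hy = dz * e2[0] - dx * e2[2]
    hz = dx * e2[1] - dy * e2[0]
    det = e1[0] * hx + e1[1] * hy + e1[2] * hz
    if -1e-14 < det < 1e-14:
        return -1.0
    f = 1.0 / det
    sx = ox - p0[0]
    sy = oy - p0[1]
    sz = oz - p0[2]
    u = f * (sx * hx + sy * hy + sz * hz)
    if u < 0.0 or u > 1.0:
        return -1.0
    qx = sy * e1[2] - sz * e1[1]
    qy = sz * e1[0] - sx * e1[2]
    qz = sx * e1[1] - sy * e1[0]
    v = f * (dx * qx + dy * qy + dz * qz)
    if v < 0.0 or v > 1.0:
        return -1.0
    t = f * (e2[0] * qx + e2[1] * qy + e2[2] * qz)
    if t <= _EPS or t >= t_max:
        return -1.0
    return t


@njit(cache=True)
def _cosine_hemisphere(nx, ny, nz):
    """Cosine-weighted direction in the hemisphere around unit normal n."""
    r1 = np.random.random()
    r2 = np.random.random()
    phi = 2.0 * np.pi * r1
    sr = np.sqrt(r2)
    x = sr * np.cos(phi)
    y = sr * np.sin(phi)
    z = np.sqrt(max(0.0, 1.0 - r2))
    # orthonormal frame around n
    if abs(nx) > 0.9:
        tx, ty, tz = 0.0, 1.0, 0.0
    else:
        tx, ty, tz = 1.0, 0.0, 0.0
    ux = ny * tz - nz * ty
    uy = nz * tx - nx * tz
    uz = nx * ty - ny * tx
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = ny * uz - nz * uy
    vy = nz * ux - nx * uz
    vz = nx * uy - ny * ux
    dx = x * ux + y * vx + z * nx
    dy = x * uy + y * vy + z * ny
    dz = x * uz + y * vz + z * nz
    return dx, dy, dz


@njit(cache=True)
def trace_kernel(
    # plant-local parallelograms
    p0,
    e1,
    e2,
    nrm,
    quad_rank,
    # inner BVH
    bmin,
    bmax,
    left,
    right,
    nstart,
    ncount,
    prim_idx,
    # stem cylinder segments (shared vertical axis through the plant origin)
    cyl_z0,
    cyl_z1,
    cyl_rank,
    cyl_radius,
    # instances
    inst_off,
    inst_min,
    inst_max,
    # sources
    src_dir,
    src_n,
    src_energy,
    launch_x0,
    launch_y0,
    launch_w,
    launch_h,
    z_top,
    # optics
    rho,
    tau,
    depth,
    seed,
    use_bvh,
    # outputs (ni, n_rank_slots)
    abs_leaf,
    abs_cyl,
):
    np.random.seed(seed)
    soil = 0.0
    escaped = 0.0
    truncated = 0.0
    emitted = 0.0
    ni = inst_off.shape[0]
    nq = p0.shape[0]
    ncyl = cyl_z0.shape[0]
    stack = np.empty(_STACK, np.int64)

    for s in range(src_dir.shape[0]):
        dx0 = src_dir[s, 0]
        dy0 = src_dir[s, 1]
        dz0 = src_dir[s, 2]
        energy = src_energy[s]
        for _ in range(src_n[s]):
            emitted += energy
            ox = launch_x0[s] + np.random.random() * launch_w[s]
            oy = launch_y0[s] + np.random.random() * launch_h[s]
            oz = z_top
            dx, dy, dz = dx0, dy0, dz0
            scatters = 0
            alive = True
            while alive:
                ix = 1.0 / dx if abs(dx) > 1e-300 else 1e300
                iy = 1.0 / dy if abs(dy) > 1e-300 else 1e300
                iz = 1.0 / dz if abs(dz) > 1e-300 else 1e300
                t_best = 1e30
                hit_inst = -1
                hit_quad = -1
                hit_cyl = -1
                if dz < 0.0:
                    t_best = (0.0 - oz) / dz  # soil plane
                for i in range(ni):
                    if not _slab_hit(inst_min[i], inst_max[i], ox, oy, oz, ix, iy, iz, t_best):
                        continue
                    lx = ox - inst_off[i, 0]
                    ly = oy - inst_off[i, 1]
                    lz = oz - inst_off[i, 2]
                    # --- panels
                    if use_bvh and nq > 0:
                        sp = 0
                        stack[0] = 0
                        sp = 1
                        while sp > 0:
                            sp -= 1
                            node = stack[sp]
                            if not _slab_hit(
                                bmin[node], bmax[node], lx, ly, lz, ix, iy, iz, t_best
                            ):
                                continue
                            if left[node] < 0:
                                for k in range(nstart[node], nstart[node] + ncount[node]):
                                    q = prim_idx[k]
                                    t = _quad_hit(
                                        p0[q], e1[q], e2[q], lx, ly, lz, dx, dy, dz, t_best
                                    )
                                    if t > 0.0:
                                        t_best = t
                                        hit_inst = i
                                        hit_quad = q
                                        hit_cyl = -1
                            else:
                                stack[sp] = left[node]
                                sp += 1
                                stack[sp] = right[node]
                                sp += 1
                    else:
                        for q in range(nq):
                            t = _quad_hit(
                                p0[q], e1[q], e2[q], lx, ly, lz, dx, dy, dz, t_best
                            )
                            if t > 0.0:
                                t_best = t
                                hit_inst = i
                                hit_quad = q
                                hit_cyl = -1
                    # --- stem cylinder segments
                    if ncyl > 0:
                        a = dx * dx + dy * dy
                        if a > 1e-14:
                            b = 2.0 * (lx * dx + ly * dy)
                            cc = lx * lx + ly * ly - cyl_radius * cyl_radius
                            disc = b * b - 4.0 * a * cc
                            if disc > 0.0:
                                sq = np.sqrt(disc)
                                for rt in range(2):
                                    t = (-b - sq) / (2.0 * a) if rt == 0 else (-b + sq) / (2.0 * a)
                                    if t <= _EPS or t >= t_best:
                                        continue
                                    z = lz + t * dz
                                    for k in range(ncyl):
                                        if cyl_z0[k] <= z < cyl_z1[k]:
                                            t_best = t
                                            hit_inst = i
                                            hit_quad = -1
                                            hit_cyl = k
                                            break
                if hit_inst < 0:
                    if dz < 0.0 and t_best < 1e30:
                        soil += energy
                    else:
                        escaped += energy
                    alive = False
                elif hit_cyl >= 0:
                    abs_cyl[hit_inst, cyl_rank[hit_cyl]] += energy
                    alive = False
                else:
                    xi = np.random.random()
                    if xi < rho + tau:
                        if scatters >= depth:
                            truncated += energy
                            alive = False
                        else:
                            scatters += 1
                            nx = nrm[hit_quad, 0]
                            ny = nrm[hit_quad, 1]
                            nz = nrm[hit_quad, 2]
                            side = dx * nx + dy * ny + dz * nz
                            if xi < rho:  # reflect: hemisphere opposing incidence
                                if side > 0.0:
                                    nx, ny, nz = -nx, -ny, -nz
                            else:  # transmit: hemisphere past the surface
                                if side < 0.0:
                                    nx, ny, nz = -nx, -ny, -nz
                            ox = ox + t_best * dx
                            oy = oy + t_best * dy
                            oz = oz + t_best * dz
                            dx, dy, dz = _cosine_hemisphere(nx, ny, nz)
                            # nudge off the surface
                            ox += 1e-7 * nx
                            oy += 1e-7 * ny
                            oz += 1e-7 * nz
                    else:
                        abs_leaf[hit_inst, quad_rank[hit_quad]] += energy
                        alive = False
    return soil, escaped, truncated, emitted
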