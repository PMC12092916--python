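"""Numba kernels for the anisotropic Eikonal fast-iterative solver.

The local update minimizes, over a tetrahedron face with known arrival times,

    t(v) = min_lambda  sum_i lambda_i t_i + || v - sum_i lambda_i x_i ||_M

where ``||d||_M = sqrt(d^T M d)`` and M is the element slowness metric
(inverse-square conduction-velocity tensor). Face, edge and vertex
sub-problems are solved in closed form (quadratics in the residual travel
time); the minimum over all sub-problems and adjacent elements is taken.
Propagation uses a label-correcting worklist: a node whose time improves by
more than ``eps`` re-activates its one-ring neighbours.
"""

import numpy as np
from numba import njit

# metric layout: M6 = (xx, yy, zz, xy, xz, yz)


@njit(cache=True, inline="always")
def _mdot(m, ax, ay, az, bx, by, bz):
    return (ax * (m[0] * bx + m[3] * by + m[4] * bz)
            + ay * (m[3] * bx + m[1] * by + m[5] * bz)
            + az * (m[4] * bx + m[5] * by + m[2] * bz))


@njit(cache=True, inline="always")
def _mnorm(m, ax, ay, az):
    v = _mdot(m, ax, ay, az, ax, ay, az)
    if v < 0.0:
        v = 0.0
    return np.sqrt(v)


@njit(cache=True)
def _edge_update(m, wx, wy, wz, px, py, pz, ta, tb):
    """Minimum over the segment x_a -> x_b (w = v - x_a, p = x_b - x_a)."""
    g = tb - ta
    A = _mdot(m, px, py, pz, px, py, pz)
    B = _mdot(m, px, py, pz, wx, wy, wz)
    C = _mdot(m, wx, wy, wz, wx, wy, wz)
    best = np.inf
    D = A - g * g
    if abs(D) > 1e-14 and A > 1e-14:
        a2 = A * D
        b2 = -2.0 * B * D
        c2 = B * B - g * g * C
        disc = b2 * b2 - 4.0 * a2 * c2
        if disc >= 0.0:
            sq = np.sqrt(disc)
            for sgn in (-1.0, 1.0):
                mu = (-b2 + sgn * sq) / (2.0 * a2)
                if 1e-9 < mu < 1.0 - 1e-9:
                    zx = wx - mu * px
                    zy = wy - mu * py
                    zz = wz - mu * pz
                    val = ta + mu * g + _mnorm(m, zx, zy, zz)
                    if val < best:
                        best = val
    return best


@njit(cache=True)
def _face_update(m, wx, wy, wz, p1x, p1y, p1z, p2x, p2y, p2z, g1, g2, t3):
    """Minimum over the interior of the face (x1, x2, x3); w = v - x3."""
    # A2 = P^T M P, b = P^T M w (2x2 system)
    a11 = _mdot(m, p1x, p1y, p1z, p1x, p1y, p1z)
    a12 = _mdot(m, p1x, p1y, p1z, p2x, p2y, p2z)
    a22 = _mdot(m, p2x, p2y, p2z, p2x, p2y, p2z)
    b1 = _mdot(m, p1x, p1y, p1z, wx, wy, wz)
    b2 = _mdot(m, p2x, p2y, p2z, wx, wy, wz)
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-18:
        return np.inf
    q1 = (a22 * b1 - a12 * b2) / det
    q2 = (a11 * b2 - a12 * b1) / det
    r1 = (a22 * g1 - a12 * g2) / det
    r2 = (a11 * g2 - a12 * g1) / det
    z0x = wx - q1 * p1x - q2 * p2x
    z0y = wy - q1 * p1y - q2 * p2y
    z0z = wz - q1 * p1z - q2 * p2z
    z1x = r1 * p1x + r2 * p2x
    z1y = r1 * p1y + r2 * p2y
    z1z = r1 * p1z + r2 * p2z
    alpha = 1.0 - _mdot(m, z1x, z1y, z1z, z1x, z1y, z1z)
    beta = -2.0 * _mdot(m, z0x, z0y, z0z, z1x, z1y, z1z)
    gamma = -_mdot(m, z0x, z0y, z0z, z0x, z0y, z0z)
    best = np.inf
    if abs(alpha) < 1e-14:
        if abs(beta) > 1e-14:
            taus = (-gamma / beta, -1.0)
        else:
            return np.inf
    else:
        disc = beta * beta - 4.0 * alpha * gamma
        if disc < 0.0:
            return np.inf
        sq = np.sqrt(disc)
        taus = ((-beta + sq) / (2.0 * alpha), (-beta - sq) / (2.0 * alpha))
    for tau in taus:
        if tau <= 0.0:
            continue
        l1 = q1 - tau * r1
        l2 = q2 - tau * r2
        if l1 >= -1e-9 and l2 >= -1e-9 and l1 + l2 <= 1.0 + 1e-9:
            val = t3 + l1 * g1 + l2 * g2 + tau
            if val < best:
                best = val
    return best


@njit(cache=True)
def _local_update(m, vx, vy, vz, xs, ts):
    """Best arrival at v through one tet face with up to 3 known times.

    ``xs`` is (3, 3) coordinates and ``ts`` length-3 times of the other
    vertices (may be inf)."""
    best = np.inf
    nfin = 0
    for i in range(3):
        if np.isfinite(ts[i]):
            nfin += 1
            cand = ts[i] + _mnorm(m, vx - xs[i, 0], vy - xs[i, 1], vz - xs[i, 2])
            if cand < best:
                best = cand
    for i in range(3):
        for j in range(i + 1, 3):
            if np.isfinite(ts[i]) and np.isfinite(ts[j]):
                cand = _edge_update(
                    m,
                    vx - xs[i, 0], vy - xs[i, 1], vz - xs[i, 2],
                    xs[j, 0] - xs[i, 0], xs[j, 1] - xs[i, 1], xs[j, 2] - xs[i, 2],
                    ts[i], ts[j])
                if cand < best:
                    best = cand
    if nfin == 3:
        cand = _face_update(
            m,
            vx - xs[2, 0], vy - xs[2, 1], vz - xs[2, 2],
            xs[0, 0] - xs[2, 0], xs[0, 1] - xs[2, 1], xs[0, 2] - xs[2, 2],
            xs[1, 0] - xs[2, 0], xs[1, 1] - xs[2, 1], xs[1, 2] - xs[2, 2],
            ts[0] - ts[2], ts[1] - ts[2], ts[2])
        if cand < best:
            best = cand
    return best


@njit(cache=True)
def fim_solve(verts, tets, m6, active_elem, indptr, adj_elems,
              src_nodes, src_times, eps, max_rounds=100000):
    """Label-correcting fast-iterative anisotropic Eikonal solve.

    Returns nodal first-arrival times (inf where unreached). ``m6`` holds the
    per-element slowness metric; elements with ``active_elem`` False are
    skipped (non-conductive)."""
    nv = verts.shape[0]
    times = np.full(nv, np.inf)
    in_next = np.zeros(nv, np.bool_)
    for s in range(src_nodes.shape[0]):
        n = src_nodes[s]
        if src_times[s] < times[n]:
            times[n] = src_times[s]
    # seed the worklist with sources and their one-ring
    for s in range(src_nodes.shape[0]):
        n = src_nodes[s]
        in_next[n] = True
        for e in adj_elems[indptr[n]:indptr[n + 1]]:
            if not active_elem[e]:
                continue
            for k in range(4):
                in_next[tets[e, k]] = True

    cur = np.empty(nv, np.int64)
    xs = np.empty((3, 3))
    ts = np.empty(3)
    for _ in range(max_rounds):
        ncur = 0
        for n in range(nv):
            if in_next[n]:
                cur[ncur] = n
                ncur += 1
                in_next[n] = False
        if ncur == 0:
            break
        for idx in range(ncur):
            node = cur[idx]
            best = times[node]
            vx, vy, vz = verts[node, 0], verts[node, 1], verts[node, 2]
            for e in adj_elems[indptr[node]:indptr[node + 1]]:
                if not active_elem[e]:
                    continue
                k = 0
                for jj in range(4):
                    o = tets[e, jj]
                    if o != node:
                        xs[k, 0] = verts[o, 0]
                        xs[k, 1] = verts[o, 1]
                        xs[k, 2] = verts[o, 2]
                        ts[k] = times[o]
                        k += 1
                if k != 3:
                    continue
                cand = _local_update(m6[e], vx, vy, vz, xs, ts)
                if cand < best:
                    best = cand
            if best < times[node] - eps:
                times[node] = best
                for e in adj_elems[indptr[node]:indptr[node + 1]]:
                    if not active_elem[e]:
                        continue
                    for k2 in range(4):
                        o = tets[e, k2]
                        if o != node:
                            in_next[o] = True
    return times
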