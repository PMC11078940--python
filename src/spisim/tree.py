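"""Serial Barnes–Hut octree for softened Coulomb forces.

Charges in the simulated plasma carry both signs (positive ions, free
electrons), so a single charge-weighted monopole per cell is ill-defined
when a cell is nearly neutral.  Each node therefore carries separate
positive and negative moments — monopole at the sign's charge centroid
plus its traceless quadrupole — so the dipole term vanishes identically
and the cell-acceptance error is third order in the opening angle
regardless of sign mixing.  Forces are softened as (r² + s²)^(3/2) in the
denominator to regularize close electron–ion encounters.

The production O(n²) direct sum lives in :mod:`spisim.dynamics`; this tree
reduces force evaluation to O(n log n) for large particle counts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import COULOMB_K

_BUCKET = 8
_MAX_DEPTH = 48


@njit(cache=True)
def _build(pos, n_particles):
    """Build the octree; returns structural arrays.

    Nodes: child index array (-1 = absent), geometric centre, half-size,
    leaf particle buckets (index -2 marks an internal node).
    """
    max_nodes = 4 * n_particles + 64
    child = np.full((max_nodes, 8), -1, dtype=np.int64)
    center = np.zeros((max_nodes, 3))
    half = np.zeros(max_nodes)
    bucket = np.full((max_nodes, _BUCKET), -1, dtype=np.int64)
    bucket_n = np.zeros(max_nodes, dtype=np.int64)
    is_leaf = np.zeros(max_nodes, dtype=np.uint8)
    overflow_next = np.full(n_particles, -1, dtype=np.int64)  # chained extras
    overflow_head = np.full(max_nodes, -1, dtype=np.int64)

    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = pos[:, d].min()
        hi[d] = pos[:, d].max()
    side = max(hi[0] - lo[0], max(hi[1] - lo[1], hi[2] - lo[2])) * 0.5 + 1e-9
    root_center = (lo + hi) * 0.5

    n_nodes = 1
    center[0] = root_center
    half[0] = side
    is_leaf[0] = 1

    for p in range(n_particles):
        node = 0
        depth = 0
        while True:
            if is_leaf[node]:
                if bucket_n[node] < _BUCKET:
                    bucket[node, bucket_n[node]] = p
                    bucket_n[node] += 1
                    break
                if depth >= _MAX_DEPTH:
                    # coincident particles: chain into the overflow list
                    overflow_next[p] = overflow_head[node]
                    overflow_head[node] = p
                    break
                # split: push existing bucket one level down
                is_leaf[node] = 0
                old = bucket[node, :bucket_n[node]].copy()
                bucket_n[node] = 0
                for k in range(old.shape[0]):
                    pp = old[k]
                    oct_ = 0
                    if pos[pp, 0] > center[node, 0]:
                        oct_ += 1
                    if pos[pp, 1] > center[node, 1]:
                        oct_ += 2
                    if pos[pp, 2] > center[node, 2]:
                        oct_ += 4
                    ch = child[node, oct_]
                    if ch == -1:
                        ch = n_nodes
                        n_nodes += 1
                        child[node, oct_] = ch
                        h = half[node] * 0.5
                        half[ch] = h
                        for d in range(3):
                            off = h if (oct_ >> d) & 1 else -h
                            center[ch, d] = center[node, d] + off
                        is_leaf[ch] = 1
                    bucket[ch, bucket_n[ch]] = pp
                    bucket_n[ch] += 1
                # fall through: reinsert current particle from this node
            oct_ = 0
            if pos[p, 0] > center[node, 0]:
                oct_ += 1
            if pos[p, 1] > center[node, 1]:
                oct_ += 2
            if pos[p, 2] > center[node, 2]:
                oct_ += 4
            ch = child[node, oct_]
            if ch == -1:
                ch = n_nodes
                n_nodes += 1
                child[node, oct_] = ch
                h = half[node] * 0.5
                half[ch] = h
                for d in range(3):
                    off = h if (oct_ >> d) & 1 else -h
                    center[ch, d] = center[node, d] + off
                is_leaf[ch] = 1
            node = ch
            depth += 1

    return (child[:n_nodes], center[:n_nodes], half[:n_nodes],
            bucket[:n_nodes], bucket_n[:n_nodes], is_leaf[:n_nodes],
            overflow_head[:n_nodes], overflow_next)


@njit(cache=True)
def _moments(pos, q, child, center, is_leaf, bucket, bucket_n,
             overflow_head, overflow_next):
    """Signed monopoles + traceless quadrupoles per node (two descents).

    Each sign's quadrupole is taken about that sign's charge centroid, so
    the dipole term vanishes identically and the leading MAC error is the
    octupole."""
    n_nodes = child.shape[0]
    qpos = np.zeros(n_nodes)
    qneg = np.zeros(n_nodes)          # stored as positive magnitude
    cpos = np.zeros((n_nodes, 3))
    cneg = np.zeros((n_nodes, 3))
    Qpos = np.zeros((n_nodes, 6))     # xx, yy, zz, xy, xz, yz
    Qneg = np.zeros((n_nodes, 6))
    for p in range(pos.shape[0]):
        qp = q[p]
        if qp == 0.0:
            continue
        node = 0
        while True:
            if qp > 0.0:
                qpos[node] += qp
                for d in range(3):
                    cpos[node, d] += qp * pos[p, d]
            else:
                qneg[node] -= qp
                for d in range(3):
                    cneg[node, d] -= qp * pos[p, d]
            if is_leaf[node]:
                break
            oct_ = 0
            if pos[p, 0] > center[node, 0]:
                oct_ += 1
            if pos[p, 1] > center[node, 1]:
                oct_ += 2
            if pos[p, 2] > center[node, 2]:
                oct_ += 4
            nxt = child[node, oct_]
            if nxt == -1:
                break
            node = nxt
    for i in range(n_nodes):
        if qpos[i] > 0.0:
            for d in range(3):
                cpos[i, d] /= qpos[i]
        if qneg[i] > 0.0:
            for d in range(3):
                cneg[i, d] /= qneg[i]
    for p in range(pos.shape[0]):
        qp = q[p]
        if qp == 0.0:
            continue
        node = 0
        while True:
            if qp > 0.0:
                dx = pos[p, 0] - cpos[node, 0]
                dy = pos[p, 1] - cpos[node, 1]
                dz = pos[p, 2] - cpos[node, 2]
                r2 = dx * dx + dy * dy + dz * dz
                Qpos[node, 0] += qp * (3.0 * dx * dx - r2)
                Qpos[node, 1] += qp * (3.0 * dy * dy - r2)
                Qpos[node, 2] += qp * (3.0 * dz * dz - r2)
                Qpos[node, 3] += qp * 3.0 * dx * dy
                Qpos[node, 4] += qp * 3.0 * dx * dz
                Qpos[node, 5] += qp * 3.0 * dy * dz
            else:
                dx = pos[p, 0] - cneg[node, 0]
                dy = pos[p, 1] - cneg[node, 1]
                dz = pos[p, 2] - cneg[node, 2]
                r2 = dx * dx + dy * dy + dz * dz
                Qneg[node, 0] -= qp * (3.0 * dx * dx - r2)
                Qneg[node, 1] -= qp * (3.0 * dy * dy - r2)
                Qneg[node, 2] -= qp * (3.0 * dz * dz - r2)
                Qneg[node, 3] -= qp * 3.0 * dx * dy
                Qneg[node, 4] -= qp * 3.0 * dx * dz
                Qneg[node, 5] -= qp * 3.0 * dy * dz
            if is_leaf[node]:
                break
            oct_ = 0
            if pos[p, 0] > center[node, 0]:
                oct_ += 1
            if pos[p, 1] > center[node, 1]:
                oct_ += 2
            if pos[p, 2] > center[node, 2]:
                oct_ += 4
            nxt = child[node, oct_]
            if nxt == -1:
                break
            node = nxt
    return qpos, qneg, cpos, cneg, Qpos, Qneg


@njit(cache=True)
def _accumulate_cell(cx, cy, cz, qs, Q, x, y, z, soft2, fx, fy, fz):
    """Monopole + traceless quadrupole field of one sign-cell at (x,y,z)."""
    dx = x - cx
    dy = y - cy
    dz = z - cz
    r2 = dx * dx + dy * dy + dz * dz + soft2
    r1 = np.sqrt(r2)
    inv3 = 1.0 / (r2 * r1)
    fx += qs * dx * inv3
    fy += qs * dy * inv3
    fz += qs * dz * inv3
    qrx = Q[0] * dx + Q[3] * dy + Q[4] * dz
    qry = Q[3] * dx + Q[1] * dy + Q[5] * dz
    qrz = Q[4] * dx + Q[5] * dy + Q[2] * dz
    rqr = dx * qrx + dy * qry + dz * qrz
    inv5 = inv3 / r2
    inv7 = inv5 / r2
    fx += -qrx * inv5 + 2.5 * rqr * dx * inv7
    fy += -qry * inv5 + 2.5 * rqr * dy * inv7
    fz += -qrz * inv5 + 2.5 * rqr * dz * inv7
    return fx, fy, fz


@njit(cache=True)
def _accumulate(px, py, pz, qs, x, y, z, soft2, fx, fy, fz):
    dx = x - px
    dy = y - py
    dz = z - pz
    r2 = dx * dx + dy * dy + dz * dz + soft2
    inv = qs / (r2 * np.sqrt(r2))
    return fx + dx * inv, fy + dy * inv, fz + dz * inv


@njit(cache=True)
def _traverse(pos, q, soften, theta,
              child, center, half, bucket, bucket_n, is_leaf,
              overflow_head, overflow_next, qpos, qneg, cpos, cneg,
              Qpos, Qneg):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    soft2 = soften * soften
    stack = np.empty(512, dtype=np.int64)
    for i in range(n):
        qi = q[i]
        if qi == 0.0:
            continue
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        top = 0
        stack[0] = 0
        top = 1
        while top > 0:
            top -= 1
            node = stack[top]
            if qpos[node] == 0.0 and qneg[node] == 0.0:
                continue
            dx = center[node, 0] - x
            dy = center[node, 1] - y
            dz = center[node, 2] - z
            dist = np.sqrt(dx * dx + dy * dy + dz * dz)
            if 2.0 * half[node] < theta * dist:
                if qpos[node] > 0.0:
                    fx, fy, fz = _accumulate_cell(cpos[node, 0], cpos[node, 1],
                                                  cpos[node, 2], qpos[node],
                                                  Qpos[node],
                                                  x, y, z, soft2, fx, fy, fz)
                if qneg[node] > 0.0:
                    fx, fy, fz = _accumulate_cell(cneg[node, 0], cneg[node, 1],
                                                  cneg[node, 2], -qneg[node],
                                                  -Qneg[node],
                                                  x, y, z, soft2, fx, fy, fz)
            elif is_leaf[node]:
                for k in range(bucket_n[node]):
                    j = bucket[node, k]
                    if j != i and q[j] != 0.0:
                        fx, fy, fz = _accumulate(pos[j, 0], pos[j, 1], pos[j, 2],
                                                 q[j], x, y, z, soft2, fx, fy, fz)
                j = overflow_head[node]
                while j != -1:
                    if j != i and q[j] != 0.0:
                        fx, fy, fz = _accumulate(pos[j, 0], pos[j, 1], pos[j, 2],
                                                 q[j], x, y, z, soft2, fx, fy, fz)
                    j = overflow_next[j]
            else:
                for c in range(8):
                    ch = child[node, c]
                    if ch != -1:
                        stack[top] = ch
                        top += 1
        # _accumulate sums q_j (r_i − r_j)/(r²+s²)^{3/2}; F_i = k q_i × that
        # (repulsive for like signs).
        forces[i, 0] = COULOMB_K * qi * fx
        forces[i, 1] = COULOMB_K * qi * fy
        forces[i, 2] = COULOMB_K * qi * fz
    return forces


def barnes_hut_forces(pos: np.ndarray, charge: np.ndarray,
                      soften: float, opening_angle: float) -> np.ndarray:
    """Approximate softened Coulomb forces (eV/Å) on every particle.

    ``opening_angle`` θ ∈ (0, 1] is the multipole acceptance criterion
    s/d < θ with s the cell side and d the distance to the cell centre;
    smaller θ opens more cells and converges to the direct sum.
    """
    if not 0.0 < opening_angle <= 1.0:
        raise ValueError("opening_angle must be in (0, 1]")
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    charge = np.ascontiguousarray(charge, dtype=np.float64)
    n = pos.shape[0]
    if n == 0:
        return np.zeros((0, 3))
    (child, center, half, bucket, bucket_n, is_leaf,
     overflow_head, overflow_next) = _build(pos, n)
    qpos, qneg, cpos, cneg, Qpos, Qneg = _moments(
        pos, charge, child, center, is_leaf, bucket, bucket_n,
        overflow_head, overflow_next)
    return _traverse(pos, charge, soften, opening_angle,
                     child, center, half, bucket, bucket_n, is_leaf,
                     overflow_head, overflow_next, qpos, qneg, cpos, cneg,
                     Qpos, Qneg)
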