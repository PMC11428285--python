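"""Numba kernels: cell lists, pairwise DPD forces, bonded and wall forces.

All kernels operate on plain NumPy arrays in reduced units and are
single-threaded so that, for a fixed seed, the stream of per-pair random
numbers — and hence the trajectory — is bit-reproducible.

Pair visiting order: each interacting pair is enumerated exactly once
(half neighbor lists over the cell grid, or an i<j double loop for boxes
too small to host a 3-cell grid).  The Gaussian variate of the random
force is drawn at that single visit and applied antisymmetrically to
both partners, which is what makes the thermostat momentum-conserving.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the integration chunk
STATUS_OK = 0
STATUS_UNSTABLE = 1
STATUS_NAN = 2

# forward half-shell of neighbor-cell offsets (13 of 26)
_OFF_X = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int64)
_OFF_Y = np.array([-1, -1, -1, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0], dtype=np.int64)
_OFF_Z = np.array([-1, 0, 1, -1, 0, 1, -1, 0, 1, -1, 0, 1, 1], dtype=np.int64)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _build_cell_list(pos, box, cutoff):
    """Counting-sort cell decomposition.

    Returns (ncells, start, order): beads of cell c are
    order[start[c]:start[c+1]], giving contiguous cell-major traversal.
    """
    n = pos.shape[0]
    nc = np.empty(3, dtype=np.int64)
    for d in range(3):
        nc[d] = max(1, int(box[d] / cutoff))
    ntot = nc[0] * nc[1] * nc[2]
    cell = np.empty(n, dtype=np.int64)
    count = np.zeros(ntot + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * nc[0]) % nc[0]
        cy = int(pos[i, 1] / box[1] * nc[1]) % nc[1]
        cz = int(pos[i, 2] / box[2] * nc[2]) % nc[2]
        if cx < 0:
            cx += nc[0]
        if cy < 0:
            cy += nc[1]
        if cz < 0:
            cz += nc[2]
        c = (cx * nc[1] + cy) * nc[2] + cz
        cell[i] = c
        count[c + 1] += 1
    start = np.empty(ntot + 1, dtype=np.int64)
    start[0] = 0
    for c in range(ntot):
        start[c + 1] = start[c] + count[c + 1]
    fill = start[:ntot].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        order[fill[cell[i]]] = i
        fill[cell[i]] += 1
    return nc, start, order


@njit(cache=True, inline="always", fastmath=True)
def _pair_kernel_one(
    i, j, pos, vel, species, amat, box, px, cutoff, gamma, sigma, inv_sqrt_dt,
    fc, fd, fr, virial,
):
    """Forces between one pair; accumulates into fc/fd/fr; returns C virial."""
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    if px:
        if dx > 0.5 * box[0]:
            dx -= box[0]
        elif dx < -0.5 * box[0]:
            dx += box[0]
    if dy > 0.5 * box[1]:
        dy -= box[1]
    elif dy < -0.5 * box[1]:
        dy += box[1]
    if dz > 0.5 * box[2]:
        dz -= box[2]
    elif dz < -0.5 * box[2]:
        dz += box[2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= cutoff * cutoff:
        return
    a = amat[species[i], species[j]]
    r = np.sqrt(r2)
    if r < 1e-12:
        # soft potential: overlapping beads repel along a random direction
        gx = np.random.normal()
        gy = np.random.normal()
        gz = np.random.normal()
        gn = np.sqrt(gx * gx + gy * gy + gz * gz)
        if gn < 1e-12:
            gx, gy, gz, gn = 1.0, 0.0, 0.0, 1.0
        ex, ey, ez = gx / gn, gy / gn, gz / gn
        fmag = a
        fc[i, 0] += fmag * ex
        fc[i, 1] += fmag * ey
        fc[i, 2] += fmag * ez
        fc[j, 0] -= fmag * ex
        fc[j, 1] -= fmag * ey
        fc[j, 2] -= fmag * ez
        return
    w = 1.0 - r / cutoff  # omega^C = omega^R; omega^D = w^2
    ex, ey, ez = dx / r, dy / r, dz / r
    # conservative
    fmag = a * w
    fc[i, 0] += fmag * ex
    fc[i, 1] += fmag * ey
    fc[i, 2] += fmag * ez
    fc[j, 0] -= fmag * ex
    fc[j, 1] -= fmag * ey
    fc[j, 2] -= fmag * ez
    virial[0] += fmag * r
    # dissipative: -gamma w^2 (e . v_ij) e
    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    ev = ex * dvx + ey * dvy + ez * dvz
    dmag = -gamma * w * w * ev
    fd[i, 0] += dmag * ex
    fd[i, 1] += dmag * ey
    fd[i, 2] += dmag * ez
    fd[j, 0] -= dmag * ex
    fd[j, 1] -= dmag * ey
    fd[j, 2] -= dmag * ez
    # random: sigma w zeta dt^(-1/2) e, one shared draw per pair per step
    if sigma > 0.0:
        zeta = np.random.normal()
        rmag = sigma * w * zeta * inv_sqrt_dt
        fr[i, 0] += rmag * ex
        fr[i, 1] += rmag * ey
        fr[i, 2] += rmag * ez
        fr[j, 0] -= rmag * ex
        fr[j, 1] -= rmag * ey
        fr[j, 2] -= rmag * ez


@njit(cache=True, fastmath=True)
def pair_forces_kernel(
    pos, vel, species, amat, box, walled_x, cutoff, gamma, sigma, inv_sqrt_dt
):
    """All pairwise DPD forces.

    Returns (fc, fd, fr, virial) where virial is the scalar sum of
    r_ij * |F^C_ij| over interacting pairs (for the pressure estimate).
    """
    n = pos.shape[0]
    px = not walled_x
    nc, cstart, order = _build_cell_list(pos, box, cutoff)
    use_cells = (not px or nc[0] >= 3) and nc[1] >= 3 and nc[2] >= 3
    if not use_cells:
        fc = np.zeros((n, 3))
        fd = np.zeros((n, 3))
        fr = np.zeros((n, 3))
        virial = np.zeros(1)
        for i in range(n):
            for j in range(i + 1, n):
                _pair_kernel_one(
                    i, j, pos, vel, species, amat, box, px, cutoff,
                    gamma, sigma, inv_sqrt_dt, fc, fd, fr, virial,
                )
        return fc, fd, fr, virial[0]
    # gather into cell-major order for cache locality
    pos_s = np.empty((n, 3))
    vel_s = np.empty((n, 3))
    spec_s = np.empty(n, dtype=species.dtype)
    for k in range(n):
        i = order[k]
        pos_s[k, 0] = pos[i, 0]
        pos_s[k, 1] = pos[i, 1]
        pos_s[k, 2] = pos[i, 2]
        vel_s[k, 0] = vel[i, 0]
        vel_s[k, 1] = vel[i, 1]
        vel_s[k, 2] = vel[i, 2]
        spec_s[k] = species[i]
    fcs = np.zeros((n, 3))
    fds = np.zeros((n, 3))
    frs = np.zeros((n, 3))
    virial = np.zeros(1)
    # self cell (off 13) + 13 forward neighbor offsets: each pair once.
    # The pair body is written out flat here — a helper call per pair
    # costs ~10x in this innermost loop.
    half0 = 0.5 * box[0]
    half1 = 0.5 * box[1]
    half2 = 0.5 * box[2]
    cut2 = cutoff * cutoff
    for cx in range(nc[0]):
        for cy in range(nc[1]):
            for cz in range(nc[2]):
                c = (cx * nc[1] + cy) * nc[2] + cz
                a0 = cstart[c]
                a1 = cstart[c + 1]
                for off in range(14):
                    if off == 13:
                        b0 = a0
                        b1 = a1
                        same_cell = True
                    else:
                        ncx = cx + _OFF_X[off]
                        if px:
                            if ncx >= nc[0]:
                                ncx -= nc[0]
                        elif ncx >= nc[0]:
                            continue
                        ncy = cy + _OFF_Y[off]
                        if ncy < 0:
                            ncy += nc[1]
                        elif ncy >= nc[1]:
                            ncy -= nc[1]
                        ncz = cz + _OFF_Z[off]
                        if ncz < 0:
                            ncz += nc[2]
                        elif ncz >= nc[2]:
                            ncz -= nc[2]
                        c2 = (ncx * nc[1] + ncy) * nc[2] + ncz
                        b0 = cstart[c2]
                        b1 = cstart[c2 + 1]
                        same_cell = False
                    for k1 in range(a0, a1):
                        x1 = pos_s[k1, 0]
                        y1 = pos_s[k1, 1]
                        z1 = pos_s[k1, 2]
                        j0 = k1 + 1 if same_cell else b0
                        for k2 in range(j0, b1):
                            dx = x1 - pos_s[k2, 0]
                            dy = y1 - pos_s[k2, 1]
                            dz = z1 - pos_s[k2, 2]
                            if px:
                                if dx > half0:
                                    dx -= box[0]
                                elif dx < -half0:
                                    dx += box[0]
                            if dy > half1:
                                dy -= box[1]
                            elif dy < -half1:
                                dy += box[1]
                            if dz > half2:
                                dz -= box[2]
                            elif dz < -half2:
                                dz += box[2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= cut2:
                                continue
                            a = amat[spec_s[k1], spec_s[k2]]
                            r = np.sqrt(r2)
                            if r < 1e-12:
                                # overlapping beads: random direction
                                gx = np.random.normal()
                                gy = np.random.normal()
                                gz = np.random.normal()
                                gn = np.sqrt(gx * gx + gy * gy + gz * gz)
                                if gn < 1e-12:
                                    gx, gy, gz, gn = 1.0, 0.0, 0.0, 1.0
                                ex = gx / gn
                                ey = gy / gn
                                ez = gz / gn
                                fcs[k1, 0] += a * ex
                                fcs[k1, 1] += a * ey
                                fcs[k1, 2] += a * ez
                                fcs[k2, 0] -= a * ex
                                fcs[k2, 1] -= a * ey
                                fcs[k2, 2] -= a * ez
                                continue
                            w = 1.0 - r / cutoff
                            ex = dx / r
                            ey = dy / r
                            ez = dz / r
                            fmag = a * w
                            fcs[k1, 0] += fmag * ex
                            fcs[k1, 1] += fmag * ey
                            fcs[k1, 2] += fmag * ez
                            fcs[k2, 0] -= fmag * ex
                            fcs[k2, 1] -= fmag * ey
                            fcs[k2, 2] -= fmag * ez
                            virial[0] += fmag * r
                            dvx = vel_s[k1, 0] - vel_s[k2, 0]
                            dvy = vel_s[k1, 1] - vel_s[k2, 1]
                            dvz = vel_s[k1, 2] - vel_s[k2, 2]
                            ev = ex * dvx + ey * dvy + ez * dvz
                            dmag = -gamma * w * w * ev
                            fds[k1, 0] += dmag * ex
                            fds[k1, 1] += dmag * ey
                            fds[k1, 2] += dmag * ez
                            fds[k2, 0] -= dmag * ex
                            fds[k2, 1] -= dmag * ey
                            fds[k2, 2] -= dmag * ez
                            if sigma > 0.0:
                                zeta = np.random.normal()
                                rmag = sigma * w * zeta * inv_sqrt_dt
                                frs[k1, 0] += rmag * ex
                                frs[k1, 1] += rmag * ey
                                frs[k1, 2] += rmag * ez
                                frs[k2, 0] -= rmag * ex
                                frs[k2, 1] -= rmag * ey
                                frs[k2, 2] -= rmag * ez
    # scatter back to original ordering
    fc = np.zeros((n, 3))
    fd = np.zeros((n, 3))
    fr = np.zeros((n, 3))
    for k in range(n):
        i = order[k]
        fc[i, 0] = fcs[k, 0]
        fc[i, 1] = fcs[k, 1]
        fc[i, 2] = fcs[k, 2]
        fd[i, 0] = fds[k, 0]
        fd[i, 1] = fds[k, 1]
        fd[i, 2] = fds[k, 2]
        fr[i, 0] = frs[k, 0]
        fr[i, 1] = frs[k, 1]
        fr[i, 2] = frs[k, 2]
    return fc, fd, fr, virial[0]


@njit(cache=True)
def bond_forces_kernel(pos, bonds, box, walled_x, kappa, r_eq):
    """Harmonic spring forces; returns (forces, max_stretch).

    max_stretch is the largest bond length found — the caller treats a
    stretch beyond half the smallest box edge as a minimum-image error.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    px = not walled_x
    max_r = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if px:
            dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > max_r:
            max_r = r
        if r < 1e-12:
            continue
        # restoring force: magnitude kappa * |r - r_eq| toward r_eq
        fmag = -kappa * (r - r_eq) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    return f, max_r


@njit(cache=True)
def wall_forces_kernel(pos, frozen, box, a_wall, z_c):
    """Quadratic wall repulsion normal to the x boundaries.

    U(z) = A_wall (1 - z/z_c)^2 for z < z_c, with z the distance to the
    nearer x boundary; force magnitude 2 A_wall (1 - z/z_c) / z_c
    directed into the box.  Beads past a wall plane feel the clamped
    maximum force; their count is returned for diagnostics.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    fmax = 2.0 * a_wall / z_c
    n_escaped = 0
    for i in range(n):
        if frozen[i]:
            continue
        x = pos[i, 0]
        if x < 0.0:
            f[i, 0] += fmax
            n_escaped += 1
        elif x < z_c:
            f[i, 0] += 2.0 * a_wall * (1.0 - x / z_c) / z_c
        z = box[0] - x
        if z < 0.0:
            f[i, 0] -= fmax
            n_escaped += 1
        elif z < z_c:
            f[i, 0] -= 2.0 * a_wall * (1.0 - z / z_c) / z_c
    return f, n_escaped


@njit(cache=True)
def tether_forces_kernel(pos, tether_idx, anchors, kappa, box, walled_x):
    """Harmonic pull toward per-bead anchors, minimum-image in periodic
    directions so wrapped beads are pulled the short way round."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    for k in range(tether_idx.shape[0]):
        i = tether_idx[k]
        for d in range(3):
            dr = pos[i, d] - anchors[k, d]
            if d > 0 or not walled_x:
                dr -= box[d] * np.round(dr / box[d])
            f[i, d] += -kappa * dr
    return f


@njit(cache=True)
def total_forces(
    pos, vel, species, amat, bonds, box, walled_x, frozen,
    cutoff, gamma, sigma, inv_sqrt_dt, kappa, r_eq, a_wall, z_c,
    tether_idx, tether_anchors, tether_k,
):
    fc, fd, fr, virial = pair_forces_kernel(
        pos, vel, species, amat, box, walled_x, cutoff, gamma, sigma, inv_sqrt_dt
    )
    f = fc + fd + fr
    if bonds.shape[0] > 0:
        fb, max_r = bond_forces_kernel(pos, bonds, box, walled_x, kappa, r_eq)
        f += fb
    else:
        max_r = 0.0
    if walled_x:
        fw, _ = wall_forces_kernel(pos, frozen, box, a_wall, z_c)
        f += fw
    if tether_idx.shape[0] > 0:
        f += tether_forces_kernel(pos, tether_idx, tether_anchors, tether_k, box, walled_x)
    return f, max_r, virial


@njit(cache=True)
def run_chunk(
    pos, vel, species, amat, bonds, box, walled_x, frozen,
    n_steps, dt, lam, cutoff, gamma, sigma, kappa, r_eq, a_wall, z_c,
    tether_idx, tether_anchors, tether_k,
):
    """Advance the system ``n_steps`` with the modified velocity-Verlet.

    Scheme (lambda-weighted velocity prediction for the dissipative
    force):

        r(t+dt)  = r + dt v + dt^2/2 f
        v~       = v + lam dt f
        f(t+dt)  = F(r(t+dt), v~)
        v(t+dt)  = v + dt/2 (f + f(t+dt))

    Frozen beads never move.  Mutates pos/vel in place; returns a status
    code (stability: a per-step displacement larger than the cutoff, or
    a NaN, aborts).
    """
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    half_min_edge = 0.5 * min(box[0], box[1], box[2])
    f, max_r, _ = total_forces(
        pos, vel, species, amat, bonds, box, walled_x, frozen,
        cutoff, gamma, sigma, inv_sqrt_dt, kappa, r_eq, a_wall, z_c,
        tether_idx, tether_anchors, tether_k,
    )
    vpred = np.zeros((n, 3))
    for step in range(n_steps):
        for i in range(n):
            if frozen[i]:
                continue
            for d in range(3):
                dr = dt * vel[i, d] + 0.5 * dt * dt * f[i, d]
                if np.abs(dr) > cutoff:
                    return STATUS_UNSTABLE, step
                pos[i, d] += dr
                vpred[i, d] = vel[i, d] + lam * dt * f[i, d]
        # wrap periodic directions
        for i in range(n):
            if not walled_x:
                pos[i, 0] %= box[0]
            pos[i, 1] %= box[1]
            pos[i, 2] %= box[2]
        f_new, max_r, _ = total_forces(
            pos, vpred, species, amat, bonds, box, walled_x, frozen,
            cutoff, gamma, sigma, inv_sqrt_dt, kappa, r_eq, a_wall, z_c,
            tether_idx, tether_anchors, tether_k,
        )
        if max_r > half_min_edge:
            return STATUS_UNSTABLE, step
        for i in range(n):
            if frozen[i]:
                continue
            for d in range(3):
                vel[i, d] += 0.5 * dt * (f[i, d] + f_new[i, d])
        f = f_new
        if np.isnan(f[0, 0]) or (n > 1 and np.isnan(f[n - 1, 0])):
            return STATUS_NAN, step
    # full NaN sweep at chunk end (cheap)
    for i in range(n):
        for d in range(3):
            if np.isnan(pos[i, d]) or np.isnan(vel[i, d]):
                return STATUS_NAN, n_steps - 1
    return STATUS_OK, n_steps - 1
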