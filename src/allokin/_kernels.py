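"""Numba-compiled inner loops (DMD event loop, MSA identity clustering).

Kept separate so the rest of the package stays importable-by-reading;
every kernel has a pure-Python reference counterpart in its home module.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1.0e30
NUDGE = 1.0e-9  # post-event radial displacement, Angstrom


@njit(cache=False)
def identity_cluster_sizes(enc, identity):
    n, L = enc.shape
    counts = np.ones(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            match = 0
            denom = 0
            for c in range(L):
                a = enc[i, c]
                b = enc[j, c]
                if a >= 0 or b >= 0:
                    denom += 1
                    if a == b and a >= 0:
                        match += 1
            if denom > 0 and match >= identity * denom:
                counts[i] += 1
                counts[j] += 1
    return counts


@njit(cache=False)
def _pair_event(pos, vel, lo2, hi2, i, j):
    """Next wall-crossing time for pair (i, j) relative to now.

    Returns (dt, wall) with wall 1 = inner, 2 = outer, 0 = none.
    """
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    c2 = dx * dx + dy * dy + dz * dz
    a = vx * vx + vy * vy + vz * vz
    b = dx * vx + dy * vy + dz * vz
    best = BIG
    wall = 0
    if a <= 0.0:
        return BIG, 0
    lo = lo2[i, j]
    hi = hi2[i, j]
    # inner wall: only reachable while approaching
    if lo > 0.0 and b < 0.0:
        disc = b * b - a * (c2 - lo)
        if disc > 0.0:
            t = (-b - np.sqrt(disc)) / a
            if t < best:
                best = t
                wall = 1
    # outer wall: always reached for a tethered pair in motion
    if hi < BIG:
        disc = b * b + a * (hi - c2)
        if disc < 0.0:
            disc = 0.0
        t = (-b + np.sqrt(disc)) / a
        if t < best:
            best = t
            wall = 2
    if wall == 0:
        return BIG, 0
    if best < 0.0:
        best = 0.0
    return best, wall


@njit(cache=False)
def _refresh_particle(pos, vel, lo2, hi2, tmat, wmat, t_now, p):
    n = pos.shape[0]
    for q in range(n):
        if q == p:
            continue
        i, j = (p, q) if p < q else (q, p)
        dt, w = _pair_event(pos, vel, lo2, hi2, i, j)
        tmat[i, j] = t_now + dt if w != 0 else BIG
        wmat[i, j] = w


@njit(cache=False)
def run_dmd_kernel(pos0, vel0, lo2, hi2, tether_i, tether_j, tether_lo, tether_hi,
                   n_events, temperature, nu, snapshot_every, seed):
    """Event-driven square-well dynamics.

    Returns snapshots, snapshot event-counts, per-snapshot kinetic energy,
    per-snapshot max wall violation (Angstrom), final positions/velocities
    and the number of events actually executed.
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    vel = vel0.copy()
    t = 0.0
    tmat = np.full((n, n), BIG)
    wmat = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            dt, w = _pair_event(pos, vel, lo2, hi2, i, j)
            tmat[i, j] = dt if w != 0 else BIG
            wmat[i, j] = w
    if nu > 0.0:
        t_therm = np.random.exponential(1.0 / (nu * n))
    else:
        t_therm = BIG

    n_snap = n_events // snapshot_every
    snaps = np.empty((n_snap, n, 3))
    snap_ev = np.empty(n_snap, dtype=np.int64)
    snap_ke = np.empty(n_snap)
    snap_viol = np.empty(n_snap)
    snap_k = 0
    sqrt_t = np.sqrt(temperature)
    n_teth = tether_i.shape[0]

    ev = 0
    while ev < n_events:
        # next pair event
        best = BIG
        bi = -1
        bj = -1
        for i in range(n):
            row = tmat[i]
            for j in range(i + 1, n):
                if row[j] < best:
                    best = row[j]
                    bi = i
                    bj = j
        if t_therm < best:
            # ghost thermostat collision: resample one particle
            dt = t_therm - t
            for p in range(n):
                pos[p, 0] += vel[p, 0] * dt
                pos[p, 1] += vel[p, 1] * dt
                pos[p, 2] += vel[p, 2] * dt
            t = t_therm
            p = np.random.randint(0, n)
            vel[p, 0] = sqrt_t * np.random.standard_normal()
            vel[p, 1] = sqrt_t * np.random.standard_normal()
            vel[p, 2] = sqrt_t * np.random.standard_normal()
            _refresh_particle(pos, vel, lo2, hi2, tmat, wmat, t, p)
            t_therm = t + np.random.exponential(1.0 / (nu * n))
        elif best >= BIG:
            break  # nothing will ever move
        else:
            dt = best - t
            for p in range(n):
                pos[p, 0] += vel[p, 0] * dt
                pos[p, 1] += vel[p, 1] * dt
                pos[p, 2] += vel[p, 2] * dt
            t = best
            i = bi
            j = bj
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            nx = dx / d
            ny = dy / d
            nz = dz / d
            vrel = (vel[i, 0] - vel[j, 0]) * nx + (vel[i, 1] - vel[j, 1]) * ny \
                + (vel[i, 2] - vel[j, 2]) * nz
            # elastic hard-wall reflection, equal masses: swap the radial
            # component of the relative velocity
            vel[i, 0] -= vrel * nx
            vel[i, 1] -= vrel * ny
            vel[i, 2] -= vrel * nz
            vel[j, 0] += vrel * nx
            vel[j, 1] += vrel * ny
            vel[j, 2] += vrel * nz
            # nudge off the wall along the new direction of radial motion
            shift = NUDGE if wmat[i, j] == 1 else -NUDGE
            pos[i, 0] += 0.5 * shift * nx
            pos[i, 1] += 0.5 * shift * ny
            pos[i, 2] += 0.5 * shift * nz
            pos[j, 0] -= 0.5 * shift * nx
            pos[j, 1] -= 0.5 * shift * ny
            pos[j, 2] -= 0.5 * shift * nz
            _refresh_particle(pos, vel, lo2, hi2, tmat, wmat, t, i)
            _refresh_particle(pos, vel, lo2, hi2, tmat, wmat, t, j)
        ev += 1
        if ev % snapshot_every == 0 and snap_k < n_snap:
            for p in range(n):
                snaps[snap_k, p, 0] = pos[p, 0]
                snaps[snap_k, p, 1] = pos[p, 1]
                snaps[snap_k, p, 2] = pos[p, 2]
            snap_ev[snap_k] = ev
            ke = 0.0
            for p in range(n):
                ke += vel[p, 0] ** 2 + vel[p, 1] ** 2 + vel[p, 2] ** 2
            snap_ke[snap_k] = 0.5 * ke
            viol = 0.0
            for k in range(n_teth):
                a = tether_i[k]
                b = tether_j[k]
                dx = pos[a, 0] - pos[b, 0]
                dy = pos[a, 1] - pos[b, 1]
                dz = pos[a, 2] - pos[b, 2]
                dd = np.sqrt(dx * dx + dy * dy + dz * dz)
                if dd < tether_lo[k] and tether_lo[k] - dd > viol:
                    viol = tether_lo[k] - dd
                if dd > tether_hi[k] and dd - tether_hi[k] > viol:
                    viol = dd - tether_hi[k]
            snap_viol[snap_k] = viol
            snap_k += 1
    return (snaps[:snap_k], snap_ev[:snap_k], snap_ke[:snap_k],
            snap_viol[:snap_k], pos, vel, ev)
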