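"""Numba force/integration kernels.

The excluded-volume sum has two interchangeable paths: an O(N²) double loop
and a cell-list search with cell size equal to the cutoff. Because a
neighbor pair within ``r_cut`` can differ by at most one cell per axis, the
cell list visits exactly the same pairs as the double loop — equality is
exact up to floating summation order. ``ev_auto`` picks the cell path when
the bounding box is dense enough for it to pay off.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def harmonic_pairs(x, pairs, k, r0, f):
    """Accumulate harmonic pair forces into ``f``; return the energy."""
    e = 0.0
    if k == 0.0:
        # still report the (zero) energy without touching forces
        return 0.0
    for m in range(pairs.shape[0]):
        i = pairs[m, 0]
        j = pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        e += 0.5 * k * dr * dr
        if r > 1e-12:
            c = -k * dr / r
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[j, 0] -= c * dx
            f[j, 1] -= c * dy
            f[j, 2] -= c * dz
    return e


@njit(cache=True)
def _ev_pair(dx, dy, dz, eps, inv2s2, rc2):
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc2:
        return 0.0, 0.0
    g = eps * np.exp(-r2 * inv2s2)
    # F_i = −∇_i V = (ε/σ²)·exp(−r²/2σ²)·(x_i − x_j): finite at r = 0
    return g, g * 2.0 * inv2s2


@njit(cache=True)
def ev_brute(x, eps, sigma, rcut, f):
    """O(N²) truncated-Gaussian excluded volume; accumulates forces."""
    n = x.shape[0]
    inv2s2 = 0.5 / (sigma * sigma)
    rc2 = rcut * rcut
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            g, c = _ev_pair(dx, dy, dz, eps, inv2s2, rc2)
            if g != 0.0:
                e += g
                f[i, 0] += c * dx
                f[i, 1] += c * dy
                f[i, 2] += c * dz
                f[j, 0] -= c * dx
                f[j, 1] -= c * dy
                f[j, 2] -= c * dz
    return e


@njit(cache=True)
def _ev_cell(x, eps, sigma, rcut, f, mins, nx, ny, nz):
    n = x.shape[0]
    inv2s2 = 0.5 / (sigma * sigma)
    rc2 = rcut * rcut
    inv_cell = 1.0 / rcut
    ncell = nx * ny * nz

    cix = np.empty(n, np.int64)
    ciy = np.empty(n, np.int64)
    ciz = np.empty(n, np.int64)
    cid = np.empty(n, np.int64)
    counts = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        ax = int((x[i, 0] - mins[0]) * inv_cell)
        ay = int((x[i, 1] - mins[1]) * inv_cell)
        az = int((x[i, 2] - mins[2]) * inv_cell)
        if ax >= nx:
            ax = nx - 1
        if ay >= ny:
            ay = ny - 1
        if az >= nz:
            az = nz - 1
        cix[i] = ax
        ciy[i] = ay
        ciz[i] = az
        c = (ax * ny + ay) * nz + az
        cid[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, np.int64)
    fill = counts[:ncell].copy()
    for i in range(n):
        c = cid[i]
        order[fill[c]] = i
        fill[c] += 1

    e = 0.0
    for i in range(n):
        ax = cix[i]
        ay = ciy[i]
        az = ciz[i]
        for ox in range(-1, 2):
            bx = ax + ox
            if bx < 0 or bx >= nx:
                continue
            for oy in range(-1, 2):
                by = ay + oy
                if by < 0 or by >= ny:
                    continue
                for oz in range(-1, 2):
                    bz = az + oz
                    if bz < 0 or bz >= nz:
                        continue
                    c = (bx * ny + by) * nz + bz
                    for q in range(counts[c], counts[c + 1]):
                        j = order[q]
                        if j <= i:
                            continue
                        dx = x[i, 0] - x[j, 0]
                        dy = x[i, 1] - x[j, 1]
                        dz = x[i, 2] - x[j, 2]
                        g, cc = _ev_pair(dx, dy, dz, eps, inv2s2, rc2)
                        if g != 0.0:
                            e += g
                            f[i, 0] += cc * dx
                            f[i, 1] += cc * dy
                            f[i, 2] += cc * dz
                            f[j, 0] -= cc * dx
                            f[j, 1] -= cc * dy
                            f[j, 2] -= cc * dz
    return e


@njit(cache=True)
def ev_auto(x, eps, sigma, rcut, f):
    """Cell-list EV when the grid is worthwhile, else the O(N²) loop."""
    n = x.shape[0]
    if n < 64 or eps == 0.0:
        return ev_brute(x, eps, sigma, rcut, f)
    mins = np.empty(3)
    maxs = np.empty(3)
    for d in range(3):
        lo = x[0, d]
        hi = x[0, d]
        for i in range(1, n):
            v = x[i, d]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        mins[d] = lo
        maxs[d] = hi
    nx = int((maxs[0] - mins[0]) / rcut) + 1
    ny = int((maxs[1] - mins[1]) / rcut) + 1
    nz = int((maxs[2] - mins[2]) / rcut) + 1
    if nx * ny * nz > 8 * n + 64:
        return ev_brute(x, eps, sigma, rcut, f)
    return _ev_cell(x, eps, sigma, rcut, f, mins, nx, ny, nz)


@njit(cache=True)
def _all_forces(x, bonds, contacts, kb, r0b, kc, r0c, eps, sigma, rcut, f):
    f[:] = 0.0
    e = harmonic_pairs(x, bonds, kb, r0b, f)
    e += harmonic_pairs(x, contacts, kc, r0c, f)
    if eps > 0.0 and x.shape[0] > 1:
        e += ev_auto(x, eps, sigma, rcut, f)
    return e


@njit(cache=True)
def run_baoab(
    x, v, bonds, contacts, kb, r0b, kc, r0c, eps, sigma, rcut,
    dt, a, bnoise, noise,
):
    """Advance ``noise.shape[0]`` BAOAB Langevin steps in place.

    ``a = exp(−γ·dt)`` and ``bnoise = sqrt(kT·(1−a²))`` are precomputed;
    ``noise`` holds the standard-normal draws for the O-substep (zeros at
    kT = 0). Unit bead mass. Returns the potential energy after the last
    step.
    """
    n = x.shape[0]
    f = np.zeros_like(x)
    e = _all_forces(x, bonds, contacts, kb, r0b, kc, r0c, eps, sigma, rcut, f)
    half = 0.5 * dt
    for s in range(noise.shape[0]):
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
                x[i, d] += half * v[i, d]
                v[i, d] = a * v[i, d] + bnoise * noise[s, i, d]
                x[i, d] += half * v[i, d]
        e = _all_forces(x, bonds, contacts, kb, r0b, kc, r0c, eps, sigma, rcut, f)
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
    return e
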