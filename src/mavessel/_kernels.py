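"""Numba kernels: membrane force field, DPD pair forces, cell-list neighbor
search, integrator and reflection sweeps.

All kernels operate on flat float64/int64 arrays so that the membranes of
every cell in a simulation can be evaluated in a single call.  Forces are
exact negative gradients of the energies implemented in
:mod:`mavessel.membrane` (verified by finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# worm-like-chain + power-law repulsion bonds


@njit(cache=True)
def wlc_pow_forces(x, edge_i, edge_j, lm, kp, kbt_over_p, forces,
                   tension_cap_factor=np.inf, core_frac=0.0):
    """Accumulate bond forces; returns (energy, worst_edge).

    ``worst_edge`` is the index of an edge at or beyond its maximum extension
    (WLC divergence), or -1 if none.  For a diverged edge the extension is
    clamped at 0.999*lm so the caller can still report diagnostics.

    ``tension_cap_factor`` optionally plateaus the WLC tension at
    ``factor * kBT/p`` per edge -- a momentum-conserving dynamic safeguard
    for explicit integration of rare large excursions; infinite by default
    (exact WLC force).
    """
    energy = 0.0
    worst = -1
    for e in range(edge_i.shape[0]):
        i = edge_i[e]
        j = edge_j[e]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        xr = l / lm[e]
        if xr >= 0.999:
            worst = e
            xr = 0.999
            l = xr * lm[e]
        cp = kbt_over_p[e]
        # WLC tension (resists stretching) and its energy
        f_wlc = cp * (0.25 / ((1.0 - xr) * (1.0 - xr)) - 0.25 + xr)
        if f_wlc > tension_cap_factor * cp:
            f_wlc = tension_cap_factor * cp
        e_wlc = cp * lm[e] * 0.25 * (3.0 * xr * xr - 2.0 * xr ** 3) / (1.0 - xr)
        # power-law repulsion, exponent m = 2: E = kp/l, f = kp/l^2.
        # Below core_frac*lm the 1/l^2 law continues with constant
        # stiffness (bounded-stiffness core: explicit integration of a
        # deeply compressed edge would otherwise be unstable).
        lc = core_frac * lm[e]
        if l >= lc:
            f_pow = kp[e] / (l * l)
            e_pow = kp[e] / l
        else:
            kc = 2.0 * kp[e] / (lc * lc * lc)
            dl = lc - l
            f_pow = kp[e] / (lc * lc) + kc * dl
            e_pow = kp[e] / lc + (kp[e] / (lc * lc)) * dl + 0.5 * kc * dl * dl
        energy += e_wlc + e_pow
        fmag = (f_pow - f_wlc) / l  # >0 pushes i, j apart
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return energy, worst


# ---------------------------------------------------------------------------
# dihedral bending


@njit(cache=True)
def bending_forces(x, edge_i, edge_j, opp_p, opp_q, kb, theta0, forces):
    """Bending energy kb*(1 - cos(theta - theta0)) on each dihedral, where
    theta is the angle between the outward normals of the two triangles
    adjacent to the edge.  Returns the energy; accumulates forces."""
    energy = 0.0
    for e in range(edge_i.shape[0]):
        p = opp_p[e]
        i = edge_i[e]
        j = edge_j[e]
        q = opp_q[e]
        # torsion of the chain (p, i, j, q); theta = pi - phi
        b1x = x[i, 0] - x[p, 0]; b1y = x[i, 1] - x[p, 1]; b1z = x[i, 2] - x[p, 2]
        b2x = x[j, 0] - x[i, 0]; b2y = x[j, 1] - x[i, 1]; b2z = x[j, 2] - x[i, 2]
        b3x = x[q, 0] - x[j, 0]; b3y = x[q, 1] - x[j, 1]; b3z = x[q, 2] - x[j, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2sq = b2x * b2x + b2y * b2y + b2z * b2z
        sliver = (1e-3 * b2sq) ** 2
        if n1sq < max(sliver, 1e-24) or n2sq < max(sliver, 1e-24):
            continue  # (near-)degenerate triangle: gradient diverges
        b2n = np.sqrt(b2sq)
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        sin_phi = (cx * b2x + cy * b2y + cz * b2z) / b2n
        cos_phi = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sin_phi, cos_phi)
        theta = np.pi - phi
        dth = theta - theta0[e]
        energy += kb[e] * (1.0 - np.cos(dth))
        # dE/dphi = -kb*sin(theta - theta0)
        de_dphi = -kb[e] * np.sin(dth)
        gax = -b2n * n1x / n1sq
        gay = -b2n * n1y / n1sq
        gaz = -b2n * n1z / n1sq
        gdx = b2n * n2x / n2sq
        gdy = b2n * n2y / n2sq
        gdz = b2n * n2z / n2sq
        r1 = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
        r3 = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
        gbx = -(1.0 + r1) * gax + r3 * gdx
        gby = -(1.0 + r1) * gay + r3 * gdy
        gbz = -(1.0 + r1) * gaz + r3 * gdz
        gcx = -(1.0 + r3) * gdx + r1 * gax
        gcy = -(1.0 + r3) * gdy + r1 * gay
        gcz = -(1.0 + r3) * gdz + r1 * gaz
        forces[p, 0] -= de_dphi * gax
        forces[p, 1] -= de_dphi * gay
        forces[p, 2] -= de_dphi * gaz
        forces[i, 0] -= de_dphi * gbx
        forces[i, 1] -= de_dphi * gby
        forces[i, 2] -= de_dphi * gbz
        forces[j, 0] -= de_dphi * gcx
        forces[j, 1] -= de_dphi * gcy
        forces[j, 2] -= de_dphi * gcz
        forces[q, 0] -= de_dphi * gdx
        forces[q, 1] -= de_dphi * gdy
        forces[q, 2] -= de_dphi * gdz
    return energy


# ---------------------------------------------------------------------------
# area and volume constraints


@njit(cache=True)
def cell_area_volume(x, tri, tri_cell, n_cells):
    """Per-cell total area and signed volume from oriented triangles."""
    area = np.zeros(n_cells)
    vol = np.zeros(n_cells)
    for t in range(tri.shape[0]):
        a = tri[t, 0]
        b = tri[t, 1]
        c = tri[t, 2]
        abx = x[b, 0] - x[a, 0]; aby = x[b, 1] - x[a, 1]; abz = x[b, 2] - x[a, 2]
        acx = x[c, 0] - x[a, 0]; acy = x[c, 1] - x[a, 1]; acz = x[c, 2] - x[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        area[tri_cell[t]] += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
        # signed volume contribution a . (b x c) / 6
        bxcx = x[b, 1] * x[c, 2] - x[b, 2] * x[c, 1]
        bxcy = x[b, 2] * x[c, 0] - x[b, 0] * x[c, 2]
        bxcz = x[b, 0] * x[c, 1] - x[b, 1] * x[c, 0]
        vol[tri_cell[t]] += (x[a, 0] * bxcx + x[a, 1] * bxcy + x[a, 2] * bxcz) / 6.0
    return area, vol


@njit(cache=True)
def area_volume_forces(x, tri, tri_cell, a0_tri, ka, kv, kd, A0, V0,
                       area, vol, forces):
    """Quadratic global-area, global-volume and local-area penalties.

    ``ka, kv, kd, A0, V0`` are per-cell arrays; ``area, vol`` the current
    per-cell values from :func:`cell_area_volume`.  Returns the energy.
    """
    energy = 0.0
    n_cells = A0.shape[0]
    for cidx in range(n_cells):
        da = area[cidx] - A0[cidx]
        dv = vol[cidx] - V0[cidx]
        energy += 0.5 * ka[cidx] * da * da / A0[cidx]
        energy += 0.5 * kv[cidx] * dv * dv / V0[cidx]
    for t in range(tri.shape[0]):
        cidx = tri_cell[t]
        a = tri[t, 0]
        b = tri[t, 1]
        c = tri[t, 2]
        abx = x[b, 0] - x[a, 0]; aby = x[b, 1] - x[a, 1]; abz = x[b, 2] - x[a, 2]
        acx = x[c, 0] - x[a, 0]; acy = x[c, 1] - x[a, 1]; acz = x[c, 2] - x[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-24:
            continue
        at = 0.5 * nn
        dat = at - a0_tri[t]
        energy += 0.5 * kd[cidx] * dat * dat / a0_tri[t]
        # dE/dA_t for global + local terms
        coef = ka[cidx] * (area[cidx] - A0[cidx]) / A0[cidx] \
            + kd[cidx] * dat / a0_tri[t]
        # grad_a A = 0.5 * (b - c) x n_hat, cyclic for b, c
        nhx = nx / nn; nhy = ny / nn; nhz = nz / nn
        bcx = x[b, 0] - x[c, 0]; bcy = x[b, 1] - x[c, 1]; bcz = x[b, 2] - x[c, 2]
        cax = x[c, 0] - x[a, 0]; cay = x[c, 1] - x[a, 1]; caz = x[c, 2] - x[a, 2]
        # note: grad_b A = 0.5 (c - a) x n_hat, grad_c A = 0.5 (a - b) x n_hat
        gax = 0.5 * (bcy * nhz - bcz * nhy)
        gay = 0.5 * (bcz * nhx - bcx * nhz)
        gaz = 0.5 * (bcx * nhy - bcy * nhx)
        gbx = 0.5 * (cay * nhz - caz * nhy)
        gby = 0.5 * (caz * nhx - cax * nhz)
        gbz = 0.5 * (cax * nhy - cay * nhx)
        gcx = -gax - gbx
        gcy = -gay - gby
        gcz = -gaz - gbz
        forces[a, 0] -= coef * gax
        forces[a, 1] -= coef * gay
        forces[a, 2] -= coef * gaz
        forces[b, 0] -= coef * gbx
        forces[b, 1] -= coef * gby
        forces[b, 2] -= coef * gbz
        forces[c, 0] -= coef * gcx
        forces[c, 1] -= coef * gcy
        forces[c, 2] -= coef * gcz
        # volume gradient: grad_a V = (b x c)/6 etc.
        vcoef = kv[cidx] * (vol[cidx] - V0[cidx]) / V0[cidx]
        forces[a, 0] -= vcoef * (x[b, 1] * x[c, 2] - x[b, 2] * x[c, 1]) / 6.0
        forces[a, 1] -= vcoef * (x[b, 2] * x[c, 0] - x[b, 0] * x[c, 2]) / 6.0
        forces[a, 2] -= vcoef * (x[b, 0] * x[c, 1] - x[b, 1] * x[c, 0]) / 6.0
        forces[b, 0] -= vcoef * (x[c, 1] * x[a, 2] - x[c, 2] * x[a, 1]) / 6.0
        forces[b, 1] -= vcoef * (x[c, 2] * x[a, 0] - x[c, 0] * x[a, 2]) / 6.0
        forces[b, 2] -= vcoef * (x[c, 0] * x[a, 1] - x[c, 1] * x[a, 0]) / 6.0
        forces[c, 0] -= vcoef * (x[a, 1] * x[b, 2] - x[a, 2] * x[b, 1]) / 6.0
        forces[c, 1] -= vcoef * (x[a, 2] * x[b, 0] - x[a, 0] * x[b, 2]) / 6.0
        forces[c, 2] -= vcoef * (x[a, 0] * x[b, 1] - x[a, 1] * x[b, 0]) / 6.0
    return energy


# ---------------------------------------------------------------------------
# counter-based pairwise noise (splitmix64)


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def pair_noise(seed, step, i, j):
    """Deterministic symmetric unit-variance noise for pair (i, j) at a
    given step: uniform on [-sqrt(3), sqrt(3)), independent of evaluation
    order, identical for (i, j) and (j, i)."""
    a = min(i, j)
    b = max(i, j)
    h = _splitmix64(np.uint64(seed) ^ _splitmix64(np.uint64(step)))
    h = _splitmix64(h ^ np.uint64(a))
    h = _splitmix64(h ^ np.uint64(b))
    u = (h >> np.uint64(11)) * (1.0 / 9007199254740992.0)  # [0, 1)
    return (2.0 * u - 1.0) * 1.7320508075688772


# ---------------------------------------------------------------------------
# cell-list binning


@njit(cache=True)
def bin_particles(x, n_act, lo, hi, cutoff, periodic):
    """Assign particles to grid bins of size >= cutoff.

    Returns (dims, starts, perm): ``perm[starts[b]:starts[b+1]]`` lists the
    particles of flat bin b.  Out-of-range coordinates on non-periodic axes
    are clamped into the edge bins.
    """
    dims = np.empty(3, dtype=np.int64)
    for ax in range(3):
        dims[ax] = max(1, int((hi[ax] - lo[ax]) / cutoff))
        # two periodic bins would make +1/-1 stencil offsets coincide
        if periodic[ax] and dims[ax] == 2:
            dims[ax] = 1
    nbins = dims[0] * dims[1] * dims[2]
    binid = np.empty(n_act, dtype=np.int64)
    counts = np.zeros(nbins + 1, dtype=np.int64)
    for i in range(n_act):
        ib = 0
        for ax in range(3):
            span = hi[ax] - lo[ax]
            t = (x[i, ax] - lo[ax]) / span
            if periodic[ax]:
                t = t - np.floor(t)
            k = int(t * dims[ax])
            if k < 0:
                k = 0
            if k >= dims[ax]:
                k = dims[ax] - 1
            ib = ib * dims[ax] + k
        binid[i] = ib
        counts[ib + 1] += 1
    starts = np.cumsum(counts)
    fill = starts[:-1].copy()
    perm = np.empty(n_act, dtype=np.int64)
    for i in range(n_act):
        perm[fill[binid[i]]] = i
        fill[binid[i]] += 1
    return dims, starts, perm


@njit(cache=True, inline="always")
def _min_image(d, span, per):
    if per and span > 0:
        if d > 0.5 * span:
            d -= span
        elif d < -0.5 * span:
            d += span
    return d


@njit(cache=True)
def neighbor_pairs(x, n_act, lo, hi, cutoff, periodic):
    """Unordered (i, j) pairs with minimum-image distance < cutoff."""
    dims, starts, perm = bin_particles(x, n_act, lo, hi, cutoff, periodic)
    span = hi - lo
    cap = max(64, n_act * 64)
    out = np.empty((cap, 2), dtype=np.int64)
    n_pairs = 0
    for bx in range(dims[0]):
        for by in range(dims[1]):
            for bz in range(dims[2]):
                b = (bx * dims[1] + by) * dims[2] + bz
                for ox in range(-1, 2):
                    cx = bx + ox
                    if periodic[0]:
                        cx %= dims[0]
                    elif cx < 0 or cx >= dims[0]:
                        continue
                    for oy in range(-1, 2):
                        cy = by + oy
                        if periodic[1]:
                            cy %= dims[1]
                        elif cy < 0 or cy >= dims[1]:
                            continue
                        for oz in range(-1, 2):
                            cz = bz + oz
                            if periodic[2]:
                                cz %= dims[2]
                            elif cz < 0 or cz >= dims[2]:
                                continue
                            nb = (cx * dims[1] + cy) * dims[2] + cz
                            for ii in range(starts[b], starts[b + 1]):
                                i = perm[ii]
                                for jj in range(starts[nb], starts[nb + 1]):
                                    j = perm[jj]
                                    if j <= i:
                                        continue
                                    dx = _min_image(x[i, 0] - x[j, 0],
                                                    span[0], periodic[0])
                                    dy = _min_image(x[i, 1] - x[j, 1],
                                                    span[1], periodic[1])
                                    dz = _min_image(x[i, 2] - x[j, 2],
                                                    span[2], periodic[2])
                                    if dx * dx + dy * dy + dz * dz \
                                            < cutoff * cutoff:
                                        if n_pairs >= cap:
                                            cap *= 2
                                            new = np.empty((cap, 2),
                                                           dtype=np.int64)
                                            new[:n_pairs] = out[:n_pairs]
                                            out = new
                                        out[n_pairs, 0] = i
                                        out[n_pairs, 1] = j
                                        n_pairs += 1
    return out[:n_pairs]


# ---------------------------------------------------------------------------
# DPD + Morse pair forces


# ---------------------------------------------------------------------------
# geometry predicate (duct + truncated-sphere saccular body)


@njit(cache=True, inline="always")
def lumen_code(px, py, pz, width, depth, cx, cy, cz, radius):
    """0 = parent duct, 1 = MA body, -1 = outside (wall material).

    The duct occupies 0 < y < width, 0 < z < depth (periodic in x); the body
    is the part of the sphere with y >= width.
    """
    if 0.0 < py < width and 0.0 < pz < depth:
        return 0
    if radius > 0.0 and py >= width:
        dx = px - cx
        dy = py - cy
        dz = pz - cz
        if dx * dx + dy * dy + dz * dz < radius * radius:
            return 1
    return -1


# ---------------------------------------------------------------------------
# integration + boundaries


@njit(cache=True)
def integrate_half1(x, v, f, xprev, ptype, n_act, dt, lo, hi, periodic):
    """First velocity-Verlet half step: v += dt/2 f; x += dt v; wrap
    periodic axes.  Wall particles (type 1) never move."""
    for i in range(n_act):
        if ptype[i] == 1:
            continue
        for ax in range(3):
            xprev[i, ax] = x[i, ax]
            v[i, ax] += 0.5 * dt * f[i, ax]
            x[i, ax] += dt * v[i, ax]
        for ax in range(3):
            if periodic[ax]:
                span = hi[ax] - lo[ax]
                if x[i, ax] >= hi[ax]:
                    x[i, ax] -= span
                elif x[i, ax] < lo[ax]:
                    x[i, ax] += span


@njit(cache=True)
def integrate_half2(v, f, ptype, n_act, dt):
    vmax2 = 0.0
    for i in range(n_act):
        if ptype[i] == 1:
            continue
        for ax in range(3):
            v[i, ax] += 0.5 * dt * f[i, ax]
        m2 = v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
        if m2 > vmax2:
            vmax2 = m2
    return np.sqrt(vmax2)


@njit(cache=True)
def wall_bounce(x, v, xprev, ptype, n_act, has_walls,
                width, depth, cx, cy, cz, radius, bounced):
    """Specular reflection at the channel wall.

    A mobile particle whose updated position left the lumen is mirrored
    back across the violated wall plane (or the spherical body wall) with
    the normal velocity component reversed; tangential motion slides.  The
    no-slip condition comes from the frozen wall particles' DPD friction.
    Falls back to a full bounce-back (position revert, velocity reversal)
    in degenerate corner cases.  Returns the number of reflections."""
    if not has_walls:
        return 0
    n = 0
    for i in range(n_act):
        if ptype[i] == 1:
            continue
        if lumen_code(x[i, 0], x[i, 1], x[i, 2],
                      width, depth, cx, cy, cz, radius) >= 0:
            continue
        n += 1
        bounced[i] = 1
        px = x[i, 0]
        py = x[i, 1]
        pz = x[i, 2]
        prev_in_body = xprev[i, 1] >= width
        if not prev_in_body:
            # duct walls: mirror across the violated planes (the previous
            # position is mirrored too, so the stored step segment becomes
            # the exact post-bounce chord for the membrane sweep)
            if py < 0.0:
                py = -py
                v[i, 1] = -v[i, 1]
                xprev[i, 1] = -xprev[i, 1]
            elif py > width:
                py = 2.0 * width - py
                v[i, 1] = -v[i, 1]
                xprev[i, 1] = 2.0 * width - xprev[i, 1]
            if pz < 0.0:
                pz = -pz
                v[i, 2] = -v[i, 2]
                xprev[i, 2] = -xprev[i, 2]
            elif pz > depth:
                pz = 2.0 * depth - pz
                v[i, 2] = -v[i, 2]
                xprev[i, 2] = 2.0 * depth - xprev[i, 2]
        else:
            # spherical body wall: fold radially
            dx = px - cx
            dy = py - cy
            dz = pz - cz
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > radius and r > 1e-12:
                fold = (2.0 * radius - r) / r
                px = cx + dx * fold
                py = cy + dy * fold
                pz = cz + dz * fold
                vr = (v[i, 0] * dx + v[i, 1] * dy + v[i, 2] * dz) / r
                v[i, 0] -= 2.0 * vr * dx / r
                v[i, 1] -= 2.0 * vr * dy / r
                v[i, 2] -= 2.0 * vr * dz / r
            elif py < width:
                # slipped out through the wall plane below the body
                py = 2.0 * width - py
                v[i, 1] = -v[i, 1]
        if lumen_code(px, py, pz, width, depth, cx, cy, cz, radius) >= 0:
            x[i, 0] = px
            x[i, 1] = py
            x[i, 2] = pz
        else:
            # degenerate corner: revert and reverse
            for ax in range(3):
                x[i, ax] = xprev[i, ax]
                v[i, ax] = -v[i, ax]
    return n


@njit(cache=True)
def membrane_reflect(x, v, xprev, ptype, n_act, tri, xtri, xtri_old,
                     n_tri_act, lo, hi, periodic, grid_cut, vcap,
                     done_flags):
    """Reflect solvent particles off membrane faces (impermeability).

    For each solvent particle, the displacement segment of this step is
    tested against nearby triangles (hash grid over triangle centroids) in
    each face's co-moving frame -- the face translation over the step is
    subtracted from the particle displacement, so a face sweeping past a
    slow particle is still detected.  On intersection the particle
    reflects specularly off the end-of-step face and the impulse is
    applied to the face's vertices by barycentric weights.  Returns the
    number of reflections."""
    if n_tri_act == 0:
        return 0
    # bin triangle centroids
    cent = np.empty((n_tri_act, 3))
    for t in range(n_tri_act):
        for ax in range(3):
            cent[t, ax] = (xtri[tri[t, 0], ax] + xtri[tri[t, 1], ax]
                           + xtri[tri[t, 2], ax]) / 3.0
        # fold into the primary image along periodic axes
        for ax in range(3):
            if periodic[ax]:
                span = hi[ax] - lo[ax]
                while cent[t, ax] >= hi[ax]:
                    cent[t, ax] -= span
                while cent[t, ax] < lo[ax]:
                    cent[t, ax] += span
    dims, starts, perm = bin_particles(cent, n_tri_act, lo, hi, grid_cut,
                                       periodic)
    span = hi - lo
    # 27-neighborhood occupancy mask: most solvent is far from any
    # membrane and skips the triangle scan entirely
    nbins = dims[0] * dims[1] * dims[2]
    near = np.zeros(nbins, dtype=np.bool_)
    for bx in range(dims[0]):
        for by in range(dims[1]):
            for bz in range(dims[2]):
                b = (bx * dims[1] + by) * dims[2] + bz
                if starts[b + 1] == starts[b]:
                    continue
                for ox in range(-1, 2):
                    cx = bx + ox
                    if periodic[0] and dims[0] > 1:
                        cx %= dims[0]
                    elif cx < 0 or cx >= dims[0]:
                        continue
                    for oy in range(-1, 2):
                        cy = by + oy
                        if periodic[1] and dims[1] > 1:
                            cy %= dims[1]
                        elif cy < 0 or cy >= dims[1]:
                            continue
                        for oz in range(-1, 2):
                            cz = bz + oz
                            if periodic[2] and dims[2] > 1:
                                cz %= dims[2]
                            elif cz < 0 or cz >= dims[2]:
                                continue
                            near[(cx * dims[1] + cy) * dims[2] + cz] = True
    n_ref = 0
    for i in range(n_act):
        if ptype[i] != 0 or done_flags[i] != 0:
            continue
        # locate the particle's grid bin
        idx = np.empty(3, dtype=np.int64)
        for ax in range(3):
            t_ = (x[i, ax] - lo[ax]) / span[ax]
            if periodic[ax]:
                t_ = t_ - np.floor(t_)
            k = int(t_ * dims[ax])
            if k < 0:
                k = 0
            if k >= dims[ax]:
                k = dims[ax] - 1
            idx[ax] = k
        if not near[(idx[0] * dims[1] + idx[1]) * dims[2] + idx[2]]:
            continue
        hit_t = 2.0
        hit_tri = -1
        hw = 0.0
        hu = 0.0
        hv_ = 0.0
        for ox in range(-1, 2):
            cxb = idx[0] + ox
            if periodic[0]:
                cxb %= dims[0]
            elif cxb < 0 or cxb >= dims[0]:
                continue
            for oy in range(-1, 2):
                cyb = idx[1] + oy
                if periodic[1]:
                    cyb %= dims[1]
                elif cyb < 0 or cyb >= dims[1]:
                    continue
                for oz in range(-1, 2):
                    czb = idx[2] + oz
                    if periodic[2]:
                        czb %= dims[2]
                    elif czb < 0 or czb >= dims[2]:
                        continue
                    nb = (cxb * dims[1] + cyb) * dims[2] + czb
                    for tt in range(starts[nb], starts[nb + 1]):
                        t = perm[tt]
                        i0 = tri[t, 0]
                        i1 = tri[t, 1]
                        i2 = tri[t, 2]
                        # face translation over the step (centroid shift)
                        shx = (xtri[i0, 0] - xtri_old[i0, 0]
                               + xtri[i1, 0] - xtri_old[i1, 0]
                               + xtri[i2, 0] - xtri_old[i2, 0]) / 3.0
                        shx = _min_image(shx, span[0], periodic[0])
                        shy = (xtri[i0, 1] - xtri_old[i0, 1]
                               + xtri[i1, 1] - xtri_old[i1, 1]
                               + xtri[i2, 1] - xtri_old[i2, 1]) / 3.0
                        shz = (xtri[i0, 2] - xtri_old[i0, 2]
                               + xtri[i1, 2] - xtri_old[i1, 2]
                               + xtri[i2, 2] - xtri_old[i2, 2]) / 3.0
                        # segment start relative to the moving face,
                        # expressed against the end-of-step face (min
                        # image relative to the triangle's first vertex)
                        ox0 = _min_image(xprev[i, 0] - xtri[i0, 0], span[0],
                                         periodic[0]) + xtri[i0, 0] + shx
                        oy0 = _min_image(xprev[i, 1] - xtri[i0, 1], span[1],
                                         periodic[1]) + xtri[i0, 1] + shy
                        oz0 = _min_image(xprev[i, 2] - xtri[i0, 2], span[2],
                                         periodic[2]) + xtri[i0, 2] + shz
                        dx_ = _min_image(x[i, 0] - xprev[i, 0], span[0],
                                         periodic[0]) - shx
                        dy_ = _min_image(x[i, 1] - xprev[i, 1], span[1],
                                         periodic[1]) - shy
                        dz_ = _min_image(x[i, 2] - xprev[i, 2], span[2],
                                         periodic[2]) - shz
                        # Moller-Trumbore
                        e1x = xtri[i1, 0] - xtri[i0, 0]
                        e1y = xtri[i1, 1] - xtri[i0, 1]
                        e1z = xtri[i1, 2] - xtri[i0, 2]
                        e2x = xtri[i2, 0] - xtri[i0, 0]
                        e2y = xtri[i2, 1] - xtri[i0, 1]
                        e2z = xtri[i2, 2] - xtri[i0, 2]
                        px_ = dy_ * e2z - dz_ * e2y
                        py_ = dz_ * e2x - dx_ * e2z
                        pz_ = dx_ * e2y - dy_ * e2x
                        det = e1x * px_ + e1y * py_ + e1z * pz_
                        if -1e-12 < det < 1e-12:
                            continue
                        inv = 1.0 / det
                        tx = ox0 - xtri[i0, 0]
                        ty = oy0 - xtri[i0, 1]
                        tz = oz0 - xtri[i0, 2]
                        u = (tx * px_ + ty * py_ + tz * pz_) * inv
                        if u < -1e-9 or u > 1.0 + 1e-9:
                            continue
                        qx = ty * e1z - tz * e1y
                        qy = tz * e1x - tx * e1z
                        qz = tx * e1y - ty * e1x
                        vv = (dx_ * qx + dy_ * qy + dz_ * qz) * inv
                        if vv < -1e-9 or u + vv > 1.0 + 1e-9:
                            continue
                        tpar = (e2x * qx + e2y * qy + e2z * qz) * inv
                        if 1e-4 <= tpar <= 1.0 and tpar < hit_t:
                            hit_t = tpar
                            hit_tri = t
                            hw = 1.0 - u - vv
                            hu = u
                            hv_ = vv
        if hit_tri >= 0:
            i0 = tri[hit_tri, 0]
            i1 = tri[hit_tri, 1]
            i2 = tri[hit_tri, 2]
            # face velocity at the hit point
            ufx = hw * v[i0, 0] + hu * v[i1, 0] + hv_ * v[i2, 0]
            ufy = hw * v[i0, 1] + hu * v[i1, 1] + hv_ * v[i2, 1]
            ufz = hw * v[i0, 2] + hu * v[i1, 2] + hv_ * v[i2, 2]
            # specular reflection of the face-normal velocity component in
            # the face frame (tangential no-slip is supplied by the DPD
            # coupling; a full bounce-back would pump the membrane)
            e1x = xtri[i1, 0] - xtri[i0, 0]
            e1y = xtri[i1, 1] - xtri[i0, 1]
            e1z = xtri[i1, 2] - xtri[i0, 2]
            e2x = xtri[i2, 0] - xtri[i0, 0]
            e2y = xtri[i2, 1] - xtri[i0, 1]
            e2z = xtri[i2, 2] - xtri[i0, 2]
            fnx = e1y * e2z - e1z * e2y
            fny = e1z * e2x - e1x * e2z
            fnz = e1x * e2y - e1y * e2x
            fnn = np.sqrt(fnx * fnx + fny * fny + fnz * fnz)
            fnx /= fnn
            fny /= fnn
            fnz /= fnn
            relx = v[i, 0] - ufx
            rely = v[i, 1] - ufy
            relz = v[i, 2] - ufz
            vn = relx * fnx + rely * fny + relz * fnz
            nvx = v[i, 0] - 2.0 * vn * fnx
            nvy = v[i, 1] - 2.0 * vn * fny
            nvz = v[i, 2] - 2.0 * vn * fnz
            # cap the face-relative speed: repeated reflections off moving
            # faces in a closing gap would otherwise pump the particle
            # (Fermi acceleration)
            rsx = nvx - ufx
            rsy = nvy - ufy
            rsz = nvz - ufz
            rsp = np.sqrt(rsx * rsx + rsy * rsy + rsz * rsz)
            capfac = 1.0
            if rsp > vcap:
                capfac = vcap / rsp
                nvx = ufx + rsx * capfac
                nvy = ufy + rsy * capfac
                nvz = ufz + rsz * capfac
            # place the particle in the face's co-moving frame: the
            # relative and absolute frames coincide at the end of the
            # step, so the reflected relative remainder gives the final
            # absolute position directly
            shx = (xtri[i0, 0] - xtri_old[i0, 0]
                   + xtri[i1, 0] - xtri_old[i1, 0]
                   + xtri[i2, 0] - xtri_old[i2, 0]) / 3.0
            shx = _min_image(shx, span[0], periodic[0])
            shy = (xtri[i0, 1] - xtri_old[i0, 1]
                   + xtri[i1, 1] - xtri_old[i1, 1]
                   + xtri[i2, 1] - xtri_old[i2, 1]) / 3.0
            shz = (xtri[i0, 2] - xtri_old[i0, 2]
                   + xtri[i1, 2] - xtri_old[i1, 2]
                   + xtri[i2, 2] - xtri_old[i2, 2]) / 3.0
            ox0 = _min_image(xprev[i, 0] - xtri[i0, 0], span[0],
                             periodic[0]) + xtri[i0, 0] + shx
            oy0 = _min_image(xprev[i, 1] - xtri[i0, 1], span[1],
                             periodic[1]) + xtri[i0, 1] + shy
            oz0 = _min_image(xprev[i, 2] - xtri[i0, 2], span[2],
                             periodic[2]) + xtri[i0, 2] + shz
            dx_ = _min_image(x[i, 0] - xprev[i, 0], span[0],
                             periodic[0]) - shx
            dy_ = _min_image(x[i, 1] - xprev[i, 1], span[1],
                             periodic[1]) - shy
            dz_ = _min_image(x[i, 2] - xprev[i, 2], span[2],
                             periodic[2]) - shz
            rem = 1.0 - hit_t
            dn = dx_ * fnx + dy_ * fny + dz_ * fnz
            rx = dx_ - 2.0 * dn * fnx
            ry = dy_ - 2.0 * dn * fny
            rz = dz_ - 2.0 * dn * fnz
            # small normal offset toward the origin side guards against
            # roundoff / face-deformation re-crossing next step
            side = -1.0 if dn > 0.0 else 1.0
            x[i, 0] = ox0 + dx_ * hit_t + rx * rem * capfac \
                + 0.02 * side * fnx
            x[i, 1] = oy0 + dy_ * hit_t + ry * rem * capfac \
                + 0.02 * side * fny
            x[i, 2] = oz0 + dz_ * hit_t + rz * rem * capfac \
                + 0.02 * side * fnz
            # store the hit point as the new segment start so a follow-up
            # sweep tests the true post-reflection sub-path (the straight
            # chord would miss neighbor-face crossings of the V path)
            xprev[i, 0] = ox0 + dx_ * hit_t
            xprev[i, 1] = oy0 + dy_ * hit_t
            xprev[i, 2] = oz0 + dz_ * hit_t
            for ax in range(3):
                if periodic[ax]:
                    sp = hi[ax] - lo[ax]
                    if x[i, ax] >= hi[ax]:
                        x[i, ax] -= sp
                    elif x[i, ax] < lo[ax]:
                        x[i, ax] += sp
            # momentum exchange with the face vertices (equal masses)
            dvx = nvx - v[i, 0]
            dvy = nvy - v[i, 1]
            dvz = nvz - v[i, 2]
            v[i, 0] = nvx
            v[i, 1] = nvy
            v[i, 2] = nvz
            v[i0, 0] -= hw * dvx
            v[i0, 1] -= hw * dvy
            v[i0, 2] -= hw * dvz
            v[i1, 0] -= hu * dvx
            v[i1, 1] -= hu * dvy
            v[i1, 2] -= hu * dvz
            v[i2, 0] -= hv_ * dvx
            v[i2, 1] -= hv_ * dvy
            v[i2, 2] -= hv_ * dvz
            done_flags[i] = 1
            n_ref += 1
    return n_ref


@njit(cache=True)
def add_body_force(f, ptype, x, n_act, g, width, parent_only):
    """Uniform driving force density along +x on solvent particles,
    optionally restricted to the parent duct (y < width)."""
    for i in range(n_act):
        if ptype[i] != 0:
            continue
        if parent_only and x[i, 1] >= width:
            continue
        f[i, 0] += g


# ---------------------------------------------------------------------------
# Verlet-list force path (hot loop of the simulation driver)

_HALF_STENCIL = np.array([
    [0, 0, 0],
    [1, -1, -1], [1, -1, 0], [1, -1, 1], [1, 0, -1], [1, 0, 0], [1, 0, 1],
    [1, 1, -1], [1, 1, 0], [1, 1, 1],
    [0, 1, -1], [0, 1, 0], [0, 1, 1],
    [0, 0, 1],
], dtype=np.int64)


@njit(cache=True, fastmath=True)
def build_pair_list(x, ptype, cellid, n_act, lo, hi, cutoff, periodic):
    """Candidate pair list within cutoff (+ caller-included skin), with
    wall-wall and same-membrane pairs excluded at build time.

    Bins of half the cutoff with a forward +-2 stencil (exact corner
    pruning) keep the candidate count low; coordinates are gathered in bin
    order so the inner scan is contiguous.
    """
    # half-cutoff bins pay off only when bins are well occupied; at low
    # density the stencil-iteration overhead dominates
    vol = (hi[0] - lo[0]) * (hi[1] - lo[1]) * (hi[2] - lo[2])
    sub = 2 if n_act / max(vol, 1e-12) * cutoff**3 > 6.0 else 1
    bs = cutoff / sub
    dims = np.empty(3, dtype=np.int64)
    for ax in range(3):
        dims[ax] = max(1, int((hi[ax] - lo[ax]) / bs))
        if periodic[ax] and dims[ax] < 2 * sub + 1:
            dims[ax] = 1  # wrap-safe degenerate binning
    nbins = dims[0] * dims[1] * dims[2]
    binid = np.empty(n_act, dtype=np.int64)
    counts = np.zeros(nbins + 1, dtype=np.int64)
    for i in range(n_act):
        ib = 0
        for ax in range(3):
            t = (x[i, ax] - lo[ax]) / (hi[ax] - lo[ax])
            if periodic[ax]:
                t -= np.floor(t)
            k = int(t * dims[ax])
            if k < 0:
                k = 0
            if k >= dims[ax]:
                k = dims[ax] - 1
            ib = ib * dims[ax] + k
        binid[i] = ib
        counts[ib + 1] += 1
    starts = np.cumsum(counts)
    fill = starts[:-1].copy()
    perm = np.empty(n_act, dtype=np.int64)
    for i in range(n_act):
        perm[fill[binid[i]]] = i
        fill[binid[i]] += 1
    xs = np.empty((n_act, 3))
    ts = np.empty(n_act, dtype=np.int64)
    cs = np.empty(n_act, dtype=np.int64)
    for k in range(n_act):
        i = perm[k]
        xs[k, 0] = x[i, 0]
        xs[k, 1] = x[i, 1]
        xs[k, 2] = x[i, 2]
        ts[k] = ptype[i]
        cs[k] = cellid[i]
    cap = max(64, n_act * 40)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    n_pairs = 0
    c2 = cutoff * cutoff
    span = hi - lo
    for bx in range(dims[0]):
        for by in range(dims[1]):
            for bz in range(dims[2]):
                b = (bx * dims[1] + by) * dims[2] + bz
                if starts[b + 1] == starts[b]:
                    continue
                for ox in range(-sub, sub + 1):
                    for oy in range(-sub, sub + 1):
                        for oz in range(-sub, sub + 1):
                            if ox < 0 or (ox == 0 and (oy < 0 or (
                                    oy == 0 and oz < 0))):
                                continue  # forward half
                            gx = max(abs(ox) - 1, 0)
                            gy = max(abs(oy) - 1, 0)
                            gz = max(abs(oz) - 1, 0)
                            if (gx * gx + gy * gy + gz * gz) * bs * bs >= c2:
                                continue  # bins cannot contain a pair
                            cx = bx + ox
                            if periodic[0] and dims[0] > 1:
                                cx %= dims[0]
                            elif cx < 0 or cx >= dims[0]:
                                continue
                            cy = by + oy
                            if periodic[1] and dims[1] > 1:
                                cy %= dims[1]
                            elif cy < 0 or cy >= dims[1]:
                                continue
                            cz = bz + oz
                            if periodic[2] and dims[2] > 1:
                                cz %= dims[2]
                            elif cz < 0 or cz >= dims[2]:
                                continue
                            nb = (cx * dims[1] + cy) * dims[2] + cz
                            same = ox == 0 and oy == 0 and oz == 0
                            if nb == b and not same:
                                continue  # tiny-box wrap onto self
                            for ii in range(starts[b], starts[b + 1]):
                                j0 = ii + 1 if same else starts[nb]
                                for jj in range(j0, starts[nb + 1]):
                                    if ts[ii] == 1 and ts[jj] == 1:
                                        continue
                                    dx = _min_image(xs[ii, 0] - xs[jj, 0],
                                                    span[0], periodic[0])
                                    dy = _min_image(xs[ii, 1] - xs[jj, 1],
                                                    span[1], periodic[1])
                                    dz = _min_image(xs[ii, 2] - xs[jj, 2],
                                                    span[2], periodic[2])
                                    if dx * dx + dy * dy + dz * dz < c2:
                                        if n_pairs >= cap:
                                            cap *= 2
                                            npi = np.empty(cap,
                                                           dtype=np.int64)
                                            npj = np.empty(cap,
                                                           dtype=np.int64)
                                            npi[:n_pairs] = pi[:n_pairs]
                                            npj[:n_pairs] = pj[:n_pairs]
                                            pi = npi
                                            pj = npj
                                        pi[n_pairs] = perm[ii]
                                        pj[n_pairs] = perm[jj]
                                        n_pairs += 1
    return pi[:n_pairs], pj[:n_pairs]


@njit(cache=True, fastmath=True)
def pair_forces_from_list(x, v, ptype, pi, pj, intra_mask, lo, hi, periodic,
                          a_mat, gamma_mat, sigma_mat, s_exp, rc,
                          a_self, r_self,
                          morse_mask, morse_de, morse_beta, morse_r0,
                          morse_rcut, seed, step, inv_sqrt_dt, forces):
    """DPD + Morse forces over a prebuilt pair list.

    ``morse_mask[k]`` marks pairs eligible for Morse adhesion (RBC vertices
    of distinct cells, when adhesion is enabled).  ``intra_mask[k]`` marks
    vertex pairs of the same membrane: they receive only a short-range
    self-contact repulsion (below ``r_self``, well under the bonded
    neighbor spacing) that keeps a folded membrane from passing through
    itself; the bonded network supplies all other intra-cell mechanics."""
    span = hi - lo
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = _min_image(x[i, 0] - x[j, 0], span[0], periodic[0])
        dy = _min_image(x[i, 1] - x[j, 1], span[1], periodic[1])
        dz = _min_image(x[i, 2] - x[j, 2], span[2], periodic[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-24:
            continue
        r = np.sqrt(r2)
        fmag = 0.0
        if r < rc:
            if intra_mask[k]:
                if r < r_self:
                    fmag += a_self * (1.0 - r / r_self)
            else:
                ti = ptype[i]
                tj = ptype[j]
                wc = 1.0 - r / rc
                fmag += a_mat[ti, tj] * wc
                g = gamma_mat[ti, tj]
                if g > 0.0:
                    wr = wc ** s_exp
                    rdotv = (dx * (v[i, 0] - v[j, 0])
                             + dy * (v[i, 1] - v[j, 1])
                             + dz * (v[i, 2] - v[j, 2])) / r
                    th = pair_noise(seed, step, i, j)
                    fmag += wr * (sigma_mat[ti, tj] * th * inv_sqrt_dt
                                  - g * wr * rdotv)
        if morse_mask[k] and r < morse_rcut:
            eb = np.exp(morse_beta * (morse_r0 - r))
            fmag += 2.0 * morse_de * morse_beta * (eb * eb - eb)
        if fmag != 0.0:
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz


@njit(cache=True)
def unwrap_cells(x, xm, cell_first, cell_nv, n_cells, L, anchors):
    """Copy membrane vertex coordinates into ``xm`` with the x coordinate
    unwrapped to the image nearest each cell's running anchor (the cell's
    unwrapped center of mass, updated in place).  Correct for cells of any
    extent below the box length, since per-step motion is tiny."""
    for c in range(n_cells):
        a = cell_first[c]
        n = cell_nv[c]
        # fold the anchor into the primary image so unwrapped coordinates
        # stay within one period of the wrapped particle positions (cells
        # circulate the channel many times)
        base = anchors[c] % L
        sx = 0.0
        for k in range(a, a + n):
            dx = x[k, 0] - base
            dx -= L * np.round(dx / L)
            ux = base + dx
            xm[k, 0] = ux
            xm[k, 1] = x[k, 1]
            xm[k, 2] = x[k, 2]
            sx += ux
        anchors[c] = sx / n


@njit(cache=True, fastmath=True)
def top2_displacement(x, x_ref, ptype, n_act):
    """Two largest mobile-particle displacements since the pair list was
    built.  A pair can close by at most their sum, so the list stays valid
    while max1 + max2 < skin."""
    m1 = 0.0
    m2 = 0.0
    for i in range(n_act):
        if ptype[i] == 1:
            continue
        dx = x[i, 0] - x_ref[i, 0]
        dy = x[i, 1] - x_ref[i, 1]
        dz = x[i, 2] - x_ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m1:
            m2 = m1
            m1 = d2
        elif d2 > m2:
            m2 = d2
    return np.sqrt(m1) + np.sqrt(m2)


@njit(cache=True, fastmath=True)
def bond_thermostat(x, v, edge_i, edge_j, gamma, sigma, seed, step,
                    inv_sqrt_dt, forces):
    """Pairwise dissipative+random thermostat along membrane bonds with
    unit weight (resolution independent: bonded neighbors may lie beyond
    the fluid cutoff).  Damps membrane oscillation modes with the correct
    thermal balance; momentum conserving."""
    for e in range(edge_i.shape[0]):
        i = edge_i[e]
        j = edge_j[e]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        ex = dx / r
        ey = dy / r
        ez = dz / r
        rdotv = ex * (v[i, 0] - v[j, 0]) + ey * (v[i, 1] - v[j, 1]) \
            + ez * (v[i, 2] - v[j, 2])
        th = pair_noise(seed + np.uint64(0x9E37), step, i, j)
        fmag = sigma * th * inv_sqrt_dt - gamma * rdotv
        forces[i, 0] += fmag * ex
        forces[i, 1] += fmag * ey
        forces[i, 2] += fmag * ez
        forces[j, 0] -= fmag * ex
        forces[j, 1] -= fmag * ey
        forces[j, 2] -= fmag * ez
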