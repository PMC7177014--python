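"""Internal force field: WCA cores, cos^2 tail attraction, bonds, bending.

All kernels are numba-compiled and operate on plain arrays.  Pair
interactions use a Verlet neighbor list built from a cell grid; the list
stores half the pairs (j > i) and Newton's third law is applied when
accumulating forces.  The pair potential between types ``ti, tj`` is

    V(r) = WCA(r; sigma_ij)                          r < 2^(1/6) sigma_ij
           -eps_ij                                   r < 2^(1/6) sigma_ij
           -eps_ij cos^2(pi (r - r_on) / (2 w_c))    r_on < r < r_on + w_c

with ``r_on = 2^(1/6) sigma_ij``; ``eps_ij`` is zero for purely repulsive
pairs, so both the potential and the force vanish continuously at the
outer cutoff.  The pairwise virial (diagonal) is accumulated for the
pressure tensor.
"""
from __future__ import annotations

import numpy as np
from numba import njit

TWO16 = 2.0 ** (1.0 / 6.0)


@njit(cache=True, fastmath=True)
def _build_neighbor_list(pos, box, rlist, mol_id, max_nbrs):
    """Half neighbor list (j > i) from a linked-cell grid; same-molecule
    pairs are excluded.  Returns (nbr, n_nbr, overflow_flag)."""
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    ncx = max(1, int(lx / rlist))
    ncy = max(1, int(ly / rlist))
    ncz = max(1, int(lz / rlist))
    # Cell size must be >= rlist for the 27-cell stencil to be complete.
    wx, wy, wz = lx / ncx, ly / ncy, lz / ncz
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int((pos[i, 0] % lx) / wx) % ncx
        iy = int((pos[i, 1] % ly) / wy) % ncy
        iz = int((pos[i, 2] % lz) / wz) % ncz
        cx[i], cy[i], cz[i] = ix, iy, iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i

    r2max = rlist * rlist
    nbr = np.empty((n, max_nbrs), dtype=np.int64)
    n_nbr = np.zeros(n, dtype=np.int64)
    overflow = False
    # per-dimension stencil offsets; a dimension spanning < 3 cells wraps
    # offsets -1 and +1 onto the same cell, so restrict the range to avoid
    # double-counting pairs
    def _offsets(nc):
        if nc >= 3:
            return np.array([-1, 0, 1], dtype=np.int64)
        if nc == 2:
            return np.array([0, 1], dtype=np.int64)
        return np.array([0], dtype=np.int64)

    offx = _offsets(ncx)
    offy = _offsets(ncy)
    offz = _offsets(ncz)
    for i in range(n):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        mi = mol_id[i]
        for ox in offx:
            jx = (cx[i] + ox) % ncx
            for oy in offy:
                jy = (cy[i] + oy) % ncy
                for oz in offz:
                    jz = (cz[i] + oz) % ncz
                    c = (jx * ncy + jy) * ncz + jz
                    j = head[c]
                    while j >= 0:
                        if j > i and mol_id[j] != mi:
                            dx = xi - pos[j, 0]
                            dy = yi - pos[j, 1]
                            dz = zi - pos[j, 2]
                            dx -= lx * np.rint(dx / lx)
                            dy -= ly * np.rint(dy / ly)
                            dz -= lz * np.rint(dz / lz)
                            if dx * dx + dy * dy + dz * dz < r2max:
                                k = n_nbr[i]
                                if k < max_nbrs:
                                    nbr[i, k] = j
                                    n_nbr[i] = k + 1
                                else:
                                    overflow = True
                        j = nxt[j]
    return nbr, n_nbr, overflow


@njit(cache=True, fastmath=True)
def _nonbonded(pos, box, nbr, n_nbr, ptype, r_on2_tab, rcut2_tab, sig2_tab,
               eps_tab, wc, forces):
    """Accumulate nonbonded forces; return (E_pot, vxx, vyy, vzz).

    The per-type-pair tables hold squared onset/cutoff radii and squared
    WCA diameters, precomputed once per system.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
    epot = 0.0
    vxx = 0.0
    vyy = 0.0
    vzz = 0.0
    pi_2wc = np.pi / (2.0 * wc)
    for i in range(n):
        ti = ptype[i]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        fxi = 0.0
        fyi = 0.0
        fzi = 0.0
        for kk in range(n_nbr[i]):
            j = nbr[i, kk]
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx > hx:
                dx -= lx
            elif dx < -hx:
                dx += lx
            if dy > hy:
                dy -= ly
            elif dy < -hy:
                dy += ly
            if dz > hz:
                dz -= lz
            elif dz < -hz:
                dz += lz
            r2 = dx * dx + dy * dy + dz * dz
            tj = ptype[j]
            if r2 >= rcut2_tab[ti, tj] or r2 < 1e-12:
                continue
            eps = eps_tab[ti, tj]
            fr = 0.0  # force magnitude / r  (F_vec = fr * d_vec on bead i)
            if r2 < r_on2_tab[ti, tj]:
                s2 = sig2_tab[ti, tj] / r2
                s6 = s2 * s2 * s2
                # WCA: V = 4(s12 - s6) + 1, F*r = 24(2 s12 - s6)
                fr = 24.0 * (2.0 * s6 * s6 - s6) / r2
                epot += 4.0 * (s6 * s6 - s6) + 1.0 - eps
            else:
                r = np.sqrt(r2)
                # V = -eps cos^2(pi t / 2) with t = (r - r_on)/wc in [0, 1];
                # sin/cos evaluated by Taylor polynomials on |x| <= pi/2
                # (|error| < 3e-6), an order of magnitude cheaper than libm
                t = (r - np.sqrt(r_on2_tab[ti, tj])) / wc
                x = np.pi * (t - 0.5)
                x2 = x * x
                sin_x = x * (
                    1.0
                    + x2
                    * (-1.0 / 6.0 + x2 * (1.0 / 120.0 + x2 * (-1.0 / 5040.0 + x2 / 362880.0)))
                )
                cos_x = 1.0 + x2 * (
                    -0.5
                    + x2
                    * (1.0 / 24.0 + x2 * (-1.0 / 720.0 + x2 * (1.0 / 40320.0 - x2 / 3628800.0)))
                )
                # cos(pi t) = -sin(x), sin(pi t) = cos(x)
                epot += -eps * 0.5 * (1.0 - sin_x)
                # dV/dr = eps * pi/(2 wc) * sin(pi t); F = -dV/dr
                fr = -eps * pi_2wc * cos_x / r
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            fxi += fx
            fyi += fy
            fzi += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            vxx += dx * fx
            vyy += dy * fy
            vzz += dz * fz
        forces[i, 0] += fxi
        forces[i, 1] += fyi
        forces[i, 2] += fzi
    return epot, vxx, vyy, vzz


@njit(cache=True, fastmath=True)
def _bonds(pos, box, bonds, bond_k, bond_r0, forces):
    """Harmonic bonds V = k/2 (r - r0)^2; returns (E, vxx, vyy, vzz)."""
    lx, ly, lz = box[0], box[1], box[2]
    epot = 0.0
    vxx = 0.0
    vyy = 0.0
    vzz = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.rint(dx / lx)
        dy -= ly * np.rint(dy / ly)
        dz -= lz * np.rint(dz / lz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        epot += 0.5 * bond_k[b] * dr * dr
        fr = -bond_k[b] * dr / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        vxx += dx * fx
        vyy += dy * fy
        vzz += dz * fz
    return epot, vxx, vyy, vzz


@njit(cache=True, fastmath=True)
def _angles(pos, box, angles, angle_k, forces):
    """Cosine bending V = k (1 + cos theta) on triplets (i, j, k), j central.

    Harmonic in the deflection from a straight chain; returns
    (E, vxx, vyy, vzz) with the virial from the two bond-vector force pairs.
    """
    lx, ly, lz = box[0], box[1], box[2]
    epot = 0.0
    vxx = 0.0
    vyy = 0.0
    vzz = 0.0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ka = angle_k[a]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ax -= lx * np.rint(ax / lx)
        ay -= ly * np.rint(ay / ly)
        az -= lz * np.rint(az / lz)
        bx -= lx * np.rint(bx / lx)
        by -= ly * np.rint(by / ly)
        bz -= lz * np.rint(bz / lz)
        ra2 = ax * ax + ay * ay + az * az
        rb2 = bx * bx + by * by + bz * bz
        ra = np.sqrt(ra2)
        rb = np.sqrt(rb2)
        dot = ax * bx + ay * by + az * bz
        ct = dot / (ra * rb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        epot += ka * (1.0 + ct)
        # dV/d(cos) = k; grad of cos theta wrt r_i: (b/ (ra rb) - ct a / ra2)
        gix = ka * -(bx / (ra * rb) - ct * ax / ra2)
        giy = ka * -(by / (ra * rb) - ct * ay / ra2)
        giz = ka * -(bz / (ra * rb) - ct * az / ra2)
        gkx = ka * -(ax / (ra * rb) - ct * bx / rb2)
        gky = ka * -(ay / (ra * rb) - ct * by / rb2)
        gkz = ka * -(az / (ra * rb) - ct * bz / rb2)
        forces[i, 0] += gix
        forces[i, 1] += giy
        forces[i, 2] += giz
        forces[k, 0] += gkx
        forces[k, 1] += gky
        forces[k, 2] += gkz
        forces[j, 0] -= gix + gkx
        forces[j, 1] -= giy + gky
        forces[j, 2] -= giz + gkz
        vxx += ax * gix + bx * gkx
        vyy += ay * giy + by * gky
        vzz += az * giz + bz * gkz
    return epot, vxx, vyy, vzz


@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref, box):
    """Max squared displacement (minimum image) between two position sets."""
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    best = 0.0
    for i in range(n):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        dx -= lx * np.rint(dx / lx)
        dy -= ly * np.rint(dy / ly)
        dz -= lz * np.rint(dz / lz)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return best


def max_pair_cutoff(pair_sigma: np.ndarray, pair_eps: np.ndarray, wc: float) -> float:
    """Largest interaction cutoff over all type pairs."""
    r_on = TWO16 * pair_sigma
    rc = np.where(pair_eps > 0.0, r_on + wc, r_on)
    return float(rc.max())


def pair_tables(
    pair_sigma: np.ndarray, pair_eps: np.ndarray, wc: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Squared onset/cutoff radii and squared diameters per type pair."""
    r_on = TWO16 * pair_sigma
    rcut = np.where(pair_eps > 0.0, r_on + wc, r_on)
    return r_on**2, rcut**2, pair_sigma**2
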