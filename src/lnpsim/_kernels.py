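"""Numba kernels: neighbour lists and force/energy evaluation.

All kernels are single-threaded and deterministic.  Distances use the
minimum-image convention in a cubic box of side ``L``.  The LJ kernel
applies a C1-continuous polynomial switching function to the potential
between ``r_on`` and the cutoff:

    S(r) = (rc^2 - r^2)^2 (rc^2 + 2 r^2 - 3 ron^2) / (rc^2 - ron^2)^3

with S(r<=ron)=1, S(r>=rc)=0 and dS/dr=0 at both ends; forces are the
exact analytic gradient of V(r)*S(r).
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _min_image(d, L):
    # valid for |d| < 1.5 L, guaranteed for wrapped positions
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def _is_excluded(i, j, excl_indptr, excl_idx):
    lo = excl_indptr[i]
    hi = excl_indptr[i + 1]
    while lo < hi:  # binary search in the sorted exclusion slice
        mid = (lo + hi) // 2
        v = excl_idx[mid]
        if v == j:
            return True
        elif v < j:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def build_pairs_n2(pos, L, rlist2, mol_id, excl_indptr, excl_idx):
    """All-pairs Verlet list (used when the box holds < 3 cells)."""
    n = pos.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            if dx * dx + dy * dy + dz * dz < rlist2:
                if mol_id[i] != mol_id[j] or not _is_excluded(i, j, excl_indptr, excl_idx):
                    count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            if dx * dx + dy * dy + dz * dz < rlist2:
                if mol_id[i] != mol_id[j] or not _is_excluded(i, j, excl_indptr, excl_idx):
                    pi[k] = i
                    pj[k] = j
                    k += 1
    return pi, pj


def build_pairs_cells(pos, L, rlist, mol_id, excl_indptr, excl_idx):
    """Cell-sorted Verlet list with half-cutoff cells.

    Beads are counting-sorted into cells of side ~rlist/2; a
    lexicographically-positive half neighbourhood (pruned by cell-cell
    minimum distance) visits every pair once.  Requires
    nc >= 2*reach + 1, which the caller guarantees by falling back to
    the all-pairs builder for small boxes.
    """
    n = pos.shape[0]
    cap = max(256, int(2.2 * rlist**3 * 12.0) * n)  # ~liquid density + margin
    while True:
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        k = _pairs_cells_kernel(pos, L, rlist, mol_id, excl_indptr, excl_idx, pi, pj)
        if k >= 0:
            return pi[:k].copy(), pj[:k].copy()
        cap *= 2


@njit(cache=True)
def _pairs_cells_kernel(pos, L, rlist, mol_id, excl_indptr, excl_idx, pi, pj):
    """Fill preallocated pair arrays; return count, or -1 on overflow."""
    n = pos.shape[0]
    nc = int(L / (0.5 * rlist))
    cell = L / nc
    reach = int(np.ceil(rlist / cell))
    rlist2 = rlist * rlist
    ncell3 = nc * nc * nc

    cidx = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell3 + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell)
        cy = int(pos[i, 1] / cell)
        cz = int(pos[i, 2] / cell)
        if cx >= nc:
            cx = nc - 1
        if cy >= nc:
            cy = nc - 1
        if cz >= nc:
            cz = nc - 1
        c3 = (cx * nc + cy) * nc + cz
        cidx[i] = c3
        counts[c3 + 1] += 1
    for c in range(ncell3):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:ncell3].copy()
    for i in range(n):
        c3 = cidx[i]
        order[fill[c3]] = i
        fill[c3] += 1
    # gather positions into cell-sorted order for contiguous inner loops
    spos = np.empty((n, 3), dtype=np.float64)
    for a in range(n):
        i = order[a]
        spos[a, 0] = pos[i, 0]
        spos[a, 1] = pos[i, 1]
        spos[a, 2] = pos[i, 2]

    # half neighbourhood: offsets lexicographically > (0,0,0), pruned by
    # the minimum distance between cells
    max_off = (2 * reach + 1) ** 3 // 2
    offs = np.empty((max_off, 3), dtype=np.int64)
    noff = 0
    for ox in range(-reach, reach + 1):
        for oy in range(-reach, reach + 1):
            for oz in range(-reach, reach + 1):
                lex_pos = (
                    ox > 0
                    or (ox == 0 and oy > 0)
                    or (ox == 0 and oy == 0 and oz > 0)
                )
                if not lex_pos:
                    continue
                gx = max(abs(ox) - 1, 0)
                gy = max(abs(oy) - 1, 0)
                gz = max(abs(oz) - 1, 0)
                if (gx * gx + gy * gy + gz * gz) * cell * cell < rlist2:
                    offs[noff, 0] = ox
                    offs[noff, 1] = oy
                    offs[noff, 2] = oz
                    noff += 1

    # precomputed neighbour-cell table (removes modulo arithmetic from
    # the inner loops)
    ctab = np.empty((ncell3, noff), dtype=np.int64)
    for cx in range(nc):
        for cy in range(nc):
            for cz in range(nc):
                c3 = (cx * nc + cy) * nc + cz
                for o in range(noff):
                    ctab[c3, o] = (
                        (((cx + offs[o, 0]) % nc) * nc
                         + ((cy + offs[o, 1]) % nc)) * nc
                        + ((cz + offs[o, 2]) % nc)
                    )

    cap = pi.size
    k = 0
    for c3 in range(ncell3):
        a0 = counts[c3]
        a1 = counts[c3 + 1]
        for a in range(a0, a1):
            i = order[a]
            xi = spos[a, 0]
            yi = spos[a, 1]
            zi = spos[a, 2]
            # same cell
            for b in range(a + 1, a1):
                dx = _min_image(xi - spos[b, 0], L)
                dy = _min_image(yi - spos[b, 1], L)
                dz = _min_image(zi - spos[b, 2], L)
                if dx * dx + dy * dy + dz * dz < rlist2:
                    j = order[b]
                    if mol_id[i] != mol_id[j] or not _is_excluded(i, j, excl_indptr, excl_idx):
                        if k >= cap:
                            return -1
                        pi[k] = i
                        pj[k] = j
                        k += 1
            # neighbour cells (half shell)
            for o in range(noff):
                c2 = ctab[c3, o]
                for b in range(counts[c2], counts[c2 + 1]):
                    dx = _min_image(xi - spos[b, 0], L)
                    dy = _min_image(yi - spos[b, 1], L)
                    dz = _min_image(zi - spos[b, 2], L)
                    if dx * dx + dy * dy + dz * dz < rlist2:
                        j = order[b]
                        if mol_id[i] != mol_id[j] or not _is_excluded(i, j, excl_indptr, excl_idx):
                            if k >= cap:
                                return -1
                            pi[k] = i
                            pj[k] = j
                            k += 1
    return k


@njit(cache=True)
def lj_energy_forces(
    pos, L, pair_i, pair_j, pair_sig2, pair_eps, r_on2, r_cut2, inv_denom, forces
):
    """Switched 12-6 LJ over a pair list.  Returns (energy, virial).

    The pair list is grouped by first index (as the builders emit it),
    letting the force on ``i`` accumulate in registers; per-pair
    ``sigma^2`` and ``eps`` are precomputed at list build time so the
    hot loop reads them sequentially.
    """
    energy = 0.0
    virial = 0.0
    n_pairs = pair_i.size
    p = 0
    while p < n_pairs:
        i = pair_i[p]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        while p < n_pairs and pair_i[p] == i:
            j = pair_j[p]
            s2 = pair_sig2[p]
            e = pair_eps[p]
            p += 1
            dx = _min_image(xi - pos[j, 0], L)
            dy = _min_image(yi - pos[j, 1], L)
            dz = _min_image(zi - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r_cut2:
                continue
            inv_r2 = 1.0 / r2
            sr2 = s2 * inv_r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            v = 4.0 * e * (sr12 - sr6)
            fs = 24.0 * e * (2.0 * sr12 - sr6) * inv_r2  # -(1/r) dV/dr
            if r2 > r_on2:
                a = r_cut2 - r2
                sw = a * a * (r_cut2 + 2.0 * r2 - 3.0 * r_on2) * inv_denom
                dsw_dr2 = 6.0 * a * (r_on2 - r2) * inv_denom
                fs = fs * sw - 2.0 * v * dsw_dr2
                v = v * sw
            energy += v
            virial += fs * r2
            fx += fs * dx
            fy += fs * dy
            fz += fs * dz
            forces[j, 0] -= fs * dx
            forces[j, 1] -= fs * dy
            forces[j, 2] -= fs * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
    return energy, virial


@njit(cache=True)
def bond_energy_forces(pos, L, bonds, r0, k, forces):
    """Harmonic bonds V = k/2 (r - r0)^2.  Returns (energy, virial)."""
    energy = 0.0
    virial = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[b]
        energy += 0.5 * k[b] * dr * dr
        fs = -k[b] * dr / r  # force on i along +d
        virial += fs * r * r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return energy, virial


@njit(cache=True)
def angle_energy_forces(pos, L, angles, cos0, k, forces):
    """Cosine-harmonic angles V = k/2 (cos(t) - cos(t0))^2."""
    energy = 0.0
    virial = 0.0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        m = angles[a, 2]
        ux = _min_image(pos[i, 0] - pos[j, 0], L)
        uy = _min_image(pos[i, 1] - pos[j, 1], L)
        uz = _min_image(pos[i, 2] - pos[j, 2], L)
        vx = _min_image(pos[m, 0] - pos[j, 0], L)
        vy = _min_image(pos[m, 1] - pos[j, 1], L)
        vz = _min_image(pos[m, 2] - pos[j, 2], L)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        dot = ux * vx + uy * vy + uz * vz
        c = dot / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        diff = c - cos0[a]
        energy += 0.5 * k[a] * diff * diff
        g = -k[a] * diff  # -dV/dcos
        # dcos/du = v/(|u||v|) - cos * u/|u|^2
        fiux = g * (vx / (nu * nv) - c * ux / (nu * nu))
        fiuy = g * (vy / (nu * nv) - c * uy / (nu * nu))
        fiuz = g * (vz / (nu * nv) - c * uz / (nu * nu))
        fmvx = g * (ux / (nu * nv) - c * vx / (nv * nv))
        fmvy = g * (uy / (nu * nv) - c * vy / (nv * nv))
        fmvz = g * (uz / (nu * nv) - c * vz / (nv * nv))
        forces[i, 0] += fiux
        forces[i, 1] += fiuy
        forces[i, 2] += fiuz
        forces[m, 0] += fmvx
        forces[m, 1] += fmvy
        forces[m, 2] += fmvz
        forces[j, 0] -= fiux + fmvx
        forces[j, 1] -= fiuy + fmvy
        forces[j, 2] -= fiuz + fmvz
        virial += fiux * ux + fiuy * uy + fiuz * uz
        virial += fmvx * vx + fmvy * vy + fmvz * vz
    return energy, virial
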