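"""Numba-jitted Metropolis Monte Carlo core.

One MC step attempts, in freshly randomized order:
  * N local moves per chain (kink-jump on interior segments, end-rotation on
    the two terminal segments),
  * one crankshaft, one whole-chain translation and one pivot per chain,
  * one Kawasaki nearest-neighbor exchange per charged lipid.

Every acceptance uses an incremental energy difference; the running total is
re-synchronized against a full recomputation at each recorded frame and the
maximum bookkeeping drift is reported.  All coordinates are in units of the
segment diameter d, energies in k_B T.  Chain coordinates are stored
unwrapped; periodic wrapping enters only through minimum-image distances
(and a whole-chain re-centering after accepted translations, which leaves
every minimum-image distance unchanged).

Move-type indices in the attempt/accept counters:
0 local, 1 crankshaft, 2 translate, 3 pivot, 4 kawasaki.
"""

import math

import numpy as np
from numba import njit

# headgroup valence by species code (PC, PS, PIP2)
_VAL = (0.0, -1.0, -4.0)
HARD_CORE_TOL = 1e-9


@njit(cache=True, inline="always")
def _mi(d, box):
    return d - box * round(d / box)


@njit(cache=True, fastmath=True)
def _pair_r2(dx, dy, dz, bx, by, periodic):
    if periodic:
        dx = _mi(dx, bx)
        dy = _mi(dy, by)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, fastmath=True)
def _vertex_angle(ax, ay, az, bx_, by_, bz_, cx, cy, cz):
    # angle at vertex b between bonds b->a and b->c
    v1x, v1y, v1z = ax - bx_, ay - by_, az - bz_
    v2x, v2y, v2z = cx - bx_, cy - by_, cz - bz_
    n1 = math.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
    n2 = math.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
    c = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.acos(c)


@njit(cache=True, fastmath=True)
def _chain_bend(buf, n_beads, kappa):
    e = 0.0
    for i in range(1, n_beads - 1):
        a = _vertex_angle(
            buf[i - 1, 0], buf[i - 1, 1], buf[i - 1, 2],
            buf[i, 0], buf[i, 1], buf[i, 2],
            buf[i + 1, 0], buf[i + 1, 1], buf[i + 1, 2],
        )
        e += (a - math.pi) ** 2
    return kappa * e


@njit(cache=True, fastmath=True)
def _total_energy(
    pos, species, site_xy, charged_sites, static_xyz, static_val,
    bx, by, periodic, lb, kd, rcut2, kappa, elec_on, bend_on,
):
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    n_charged = charged_sites.shape[0]
    n_static = static_xyz.shape[0]
    u = 0.0
    if elec_on:
        # segment-segment (all unordered pairs, bonded included)
        n_tot = n_chains * n_beads
        for a in range(n_tot):
            ca, ia = a // n_beads, a % n_beads
            for b in range(a + 1, n_tot):
                cb, ib = b // n_beads, b % n_beads
                r2 = _pair_r2(
                    pos[ca, ia, 0] - pos[cb, ib, 0],
                    pos[ca, ia, 1] - pos[cb, ib, 1],
                    pos[ca, ia, 2] - pos[cb, ib, 2],
                    bx, by, periodic,
                )
                if r2 < rcut2:
                    r = math.sqrt(r2)
                    u += lb * math.exp(-kd * r) / r
        # segment-lipid
        for a in range(n_tot):
            ca, ia = a // n_beads, a % n_beads
            for q in range(n_charged):
                s = charged_sites[q]
                zz = _VAL[species[s]]
                r2 = _pair_r2(
                    pos[ca, ia, 0] - site_xy[s, 0],
                    pos[ca, ia, 1] - site_xy[s, 1],
                    pos[ca, ia, 2],
                    bx, by, periodic,
                )
                if r2 < rcut2:
                    r = math.sqrt(r2)
                    u += zz * lb * math.exp(-kd * r) / r
        # lipid-lipid
        for q in range(n_charged):
            sq = charged_sites[q]
            zq = _VAL[species[sq]]
            for p in range(q + 1, n_charged):
                sp = charged_sites[p]
                r2 = _pair_r2(
                    site_xy[sq, 0] - site_xy[sp, 0],
                    site_xy[sq, 1] - site_xy[sp, 1],
                    0.0,
                    bx, by, periodic,
                )
                if r2 < rcut2:
                    r = math.sqrt(r2)
                    u += zq * _VAL[species[sp]] * lb * math.exp(-kd * r) / r
        # static test charges against everything mobile
        for t in range(n_static):
            zt = static_val[t]
            for a in range(n_tot):
                ca, ia = a // n_beads, a % n_beads
                r2 = _pair_r2(
                    static_xyz[t, 0] - pos[ca, ia, 0],
                    static_xyz[t, 1] - pos[ca, ia, 1],
                    static_xyz[t, 2] - pos[ca, ia, 2],
                    bx, by, periodic,
                )
                if r2 < rcut2:
                    r = math.sqrt(r2)
                    u += zt * lb * math.exp(-kd * r) / r
            for q in range(n_charged):
                s = charged_sites[q]
                r2 = _pair_r2(
                    static_xyz[t, 0] - site_xy[s, 0],
                    static_xyz[t, 1] - site_xy[s, 1],
                    static_xyz[t, 2],
                    bx, by, periodic,
                )
                if r2 < rcut2:
                    r = math.sqrt(r2)
                    u += zt * _VAL[species[s]] * lb * math.exp(-kd * r) / r
    if bend_on and kappa > 0.0:
        for c in range(n_chains):
            u += _chain_bend(pos[c], n_beads, kappa)
    return u


@njit(cache=True, fastmath=True)
def _bead_external(
    pos, c, i, x, y, z,
    species, site_xy, charged_sites, static_xyz, static_val,
    bx, by, periodic, lb, kd, rcut2,
):
    """Electrostatic energy of a +1 charge at (x,y,z) with every charge except
    bead (c, i) itself."""
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    u = 0.0
    for cc in range(n_chains):
        for ii in range(n_beads):
            if cc == c and ii == i:
                continue
            r2 = _pair_r2(
                x - pos[cc, ii, 0], y - pos[cc, ii, 1], z - pos[cc, ii, 2],
                bx, by, periodic,
            )
            if r2 < rcut2:
                r = math.sqrt(r2)
                u += lb * math.exp(-kd * r) / r
    for q in range(charged_sites.shape[0]):
        s = charged_sites[q]
        r2 = _pair_r2(
            x - site_xy[s, 0], y - site_xy[s, 1], z, bx, by, periodic
        )
        if r2 < rcut2:
            r = math.sqrt(r2)
            u += _VAL[species[s]] * lb * math.exp(-kd * r) / r
    for t in range(static_xyz.shape[0]):
        r2 = _pair_r2(
            x - static_xyz[t, 0], y - static_xyz[t, 1], z - static_xyz[t, 2],
            bx, by, periodic,
        )
        if r2 < rcut2:
            r = math.sqrt(r2)
            u += static_val[t] * lb * math.exp(-kd * r) / r
    return u


@njit(cache=True, fastmath=True)
def _block_energy(
    pos, c, lo, hi, block,
    species, site_xy, charged_sites, static_xyz, static_val,
    bx, by, periodic, lb, kd, rcut2,
):
    """Electrostatic energy of beads [lo, hi) of chain c, at the coordinates
    given in ``block``, with everything outside the block plus all pairs
    within the block."""
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    m = hi - lo
    u = 0.0
    for k in range(m):
        x, y, z = block[k, 0], block[k, 1], block[k, 2]
        for cc in range(n_chains):
            for ii in range(n_beads):
                if cc == c and lo <= ii < hi:
                    continue
                r2 = _pair_r2(
                    x - pos[cc, ii, 0], y - pos[cc, ii, 1], z - pos[cc, ii, 2],
                    bx, by, periodic,
                )
                if r2 < rcut2:
                    r = math.sqrt(r2)
                    u += lb * math.exp(-kd * r) / r
        for q in range(charged_sites.shape[0]):
            s = charged_sites[q]
            r2 = _pair_r2(
                x - site_xy[s, 0], y - site_xy[s, 1], z, bx, by, periodic
            )
            if r2 < rcut2:
                r = math.sqrt(r2)
                u += _VAL[species[s]] * lb * math.exp(-kd * r) / r
        for t in range(static_xyz.shape[0]):
            r2 = _pair_r2(
                x - static_xyz[t, 0], y - static_xyz[t, 1],
                z - static_xyz[t, 2], bx, by, periodic,
            )
            if r2 < rcut2:
                r = math.sqrt(r2)
                u += static_val[t] * lb * math.exp(-kd * r) / r
        for k2 in range(k + 1, m):
            r2 = _pair_r2(
                x - block[k2, 0], y - block[k2, 1], z - block[k2, 2],
                bx, by, periodic,
            )
            if r2 < rcut2:
                r = math.sqrt(r2)
                u += lb * math.exp(-kd * r) / r
    return u


@njit(cache=True, fastmath=True)
def _bead_overlap(pos, c, i, x, y, z, bx, by, periodic, wall):
    if wall and z < 0.5:
        return True
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    lim = (1.0 - HARD_CORE_TOL) ** 2
    for cc in range(n_chains):
        for ii in range(n_beads):
            if cc == c and (ii == i or ii == i - 1 or ii == i + 1):
                continue  # self and bonded neighbors
            r2 = _pair_r2(
                x - pos[cc, ii, 0], y - pos[cc, ii, 1], z - pos[cc, ii, 2],
                bx, by, periodic,
            )
            if r2 < lim:
                return True
    return False


@njit(cache=True, fastmath=True)
def _block_overlap(pos, c, lo, hi, block, bx, by, periodic, wall):
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    lim = (1.0 - HARD_CORE_TOL) ** 2
    for k in range(hi - lo):
        i = lo + k
        x, y, z = block[k, 0], block[k, 1], block[k, 2]
        if wall and z < 0.5:
            return True
        for cc in range(n_chains):
            for ii in range(n_beads):
                if cc == c:
                    if lo <= ii < hi:
                        continue  # intra-block geometry is rigid
                    if ii == i - 1 or ii == i + 1:
                        continue  # bonds across the block boundary
                r2 = _pair_r2(
                    x - pos[cc, ii, 0], y - pos[cc, ii, 1], z - pos[cc, ii, 2],
                    bx, by, periodic,
                )
                if r2 < lim:
                    return True
    return False


@njit(cache=True, fastmath=True)
def _site_potential(
    sx, sy, skip_a, skip_b,
    pos, species, site_xy, charged_sites, static_xyz, static_val,
    bx, by, periodic, lb, kd, rcut2,
):
    """Potential sum_q Z_q phi(r) at lattice site (sx, sy, 0) from all charges
    except the lipids occupying sites skip_a and skip_b."""
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    u = 0.0
    for cc in range(n_chains):
        for ii in range(n_beads):
            r2 = _pair_r2(
                sx - pos[cc, ii, 0], sy - pos[cc, ii, 1], pos[cc, ii, 2],
                bx, by, periodic,
            )
            if r2 < rcut2:
                r = math.sqrt(r2)
                u += lb * math.exp(-kd * r) / r
    for q in range(charged_sites.shape[0]):
        s = charged_sites[q]
        if s == skip_a or s == skip_b:
            continue
        r2 = _pair_r2(
            sx - site_xy[s, 0], sy - site_xy[s, 1], 0.0, bx, by, periodic
        )
        if r2 < rcut2:
            r = math.sqrt(r2)
            u += _VAL[species[s]] * lb * math.exp(-kd * r) / r
    for t in range(static_xyz.shape[0]):
        r2 = _pair_r2(
            sx - static_xyz[t, 0], sy - static_xyz[t, 1], static_xyz[t, 2],
            bx, by, periodic,
        )
        if r2 < rcut2:
            r = math.sqrt(r2)
            u += static_val[t] * lb * math.exp(-kd * r) / r
    return u


@njit(cache=True, fastmath=True)
def _random_unit_vector():
    while True:
        a = 2.0 * np.random.random() - 1.0
        b = 2.0 * np.random.random() - 1.0
        s = a * a + b * b
        if s < 1.0:
            root = 2.0 * math.sqrt(1.0 - s)
            return a * root, b * root, 1.0 - 2.0 * s


@njit(cache=True, fastmath=True)
def _rotate_about_axis(px, py, pz, ox, oy, oz, ux, uy, uz, angle):
    """Rodrigues rotation of point p about the unit axis u through origin o."""
    vx, vy, vz = px - ox, py - oy, pz - oz
    c, s = math.cos(angle), math.sin(angle)
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    rx = vx * c + cx * s + ux * dot * (1.0 - c)
    ry = vy * c + cy * s + uy * dot * (1.0 - c)
    rz = vz * c + cz * s + uz * dot * (1.0 - c)
    return ox + rx, oy + ry, oz + rz


@njit(cache=True, fastmath=True)
def _accept(du):
    if du <= 0.0:
        return True
    return np.random.random() < math.exp(-du)


@njit(cache=True, fastmath=True)
def advance(
    pos,                # (n_chains, n_beads, 3) float64, modified in place
    species,            # (n_sites,) int8, modified in place
    site_xy,            # (n_sites, 2) float64
    neighbors,          # (n_sites, 6) int32
    charged_sites,      # (n_charged,) int32, modified in place
    site_lipid,         # (n_sites,) int32, modified in place
    static_xyz,         # (n_static, 3) float64
    static_val,         # (n_static,) float64
    bx, by,             # box dimensions (units of d); ignored if not periodic
    periodic, wall,     # booleans
    lb, kd, rcut,       # Bjerrum length, inverse Debye length, cutoff (reduced)
    kappa,              # bending rigidity (k_B T)
    elec_on, bend_on,   # stage switches (both False in the athermal stage)
    trans_delta,        # half-width of the translation cube (units of d)
    n_steps,
    record_every,       # <= 0: no frames recorded
    resync_every,       # full-energy resynchronization cadence (steps)
    seed,
    rec_pos, rec_species, rec_lipid_sites, rec_energy,  # preallocated outputs
    attempts, accepts,  # (5,) int64 counters
):
    np.random.seed(seed)
    n_chains, n_beads = pos.shape[0], pos.shape[1]
    n_charged = charged_sites.shape[0]
    rcut2 = rcut * rcut

    # static per-step move schedule; order reshuffled every step
    n_moves = n_chains * (n_beads + 3) + n_charged
    mtype = np.empty(n_moves, np.int32)
    marg = np.empty(n_moves, np.int32)
    marg2 = np.empty(n_moves, np.int32)
    k = 0
    for c in range(n_chains):
        for i in range(n_beads):
            mtype[k] = 0
            marg[k] = c
            marg2[k] = i
            k += 1
        for t in range(1, 4):
            mtype[k] = t
            marg[k] = c
            k += 1
    for q in range(n_charged):
        mtype[k] = 4
        marg[k] = q
        k += 1
    order = np.arange(n_moves)

    block = np.empty((n_beads, 3))
    chainbuf = np.empty((n_beads, 3))

    energy = _total_energy(
        pos, species, site_xy, charged_sites, static_xyz, static_val,
        bx, by, periodic, lb, kd, rcut2, kappa, elec_on, bend_on,
    )
    max_drift = 0.0
    n_rec = 0

    for step in range(n_steps):
        for a in range(n_moves - 1, 0, -1):
            b = np.random.randint(0, a + 1)
            tmp = order[a]
            order[a] = order[b]
            order[b] = tmp
        for mi in range(n_moves):
            m = order[mi]
            t = mtype[m]
            attempts[t] += 1
            if t == 0:
                # --- local: kink-jump or end-rotation -------------------
                c, i = marg[m], marg2[m]
                if 0 < i < n_beads - 1:
                    ax, ay, az = pos[c, i - 1, 0], pos[c, i - 1, 1], pos[c, i - 1, 2]
                    ux = pos[c, i + 1, 0] - ax
                    uy = pos[c, i + 1, 1] - ay
                    uz = pos[c, i + 1, 2] - az
                    un = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux, uy, uz = ux / un, uy / un, uz / un
                    angle = (2.0 * np.random.random() - 1.0) * math.pi
                    nx, ny, nz = _rotate_about_axis(
                        pos[c, i, 0], pos[c, i, 1], pos[c, i, 2],
                        ax, ay, az, ux, uy, uz, angle,
                    )
                else:
                    j = 1 if i == 0 else n_beads - 2
                    dx = pos[c, i, 0] - pos[c, j, 0]
                    dy = pos[c, i, 1] - pos[c, j, 1]
                    dz = pos[c, i, 2] - pos[c, j, 2]
                    bond = math.sqrt(dx * dx + dy * dy + dz * dz)
                    ux, uy, uz = _random_unit_vector()
                    nx = pos[c, j, 0] + bond * ux
                    ny = pos[c, j, 1] + bond * uy
                    nz = pos[c, j, 2] + bond * uz
                if _bead_overlap(pos, c, i, nx, ny, nz, bx, by, periodic, wall):
                    continue
                du = 0.0
                if elec_on:
                    du += _bead_external(
                        pos, c, i, nx, ny, nz, species, site_xy, charged_sites,
                        static_xyz, static_val, bx, by, periodic, lb, kd, rcut2,
                    ) - _bead_external(
                        pos, c, i, pos[c, i, 0], pos[c, i, 1], pos[c, i, 2],
                        species, site_xy, charged_sites,
                        static_xyz, static_val, bx, by, periodic, lb, kd, rcut2,
                    )
                if bend_on and kappa > 0.0 and n_beads >= 3:
                    for v in range(max(1, i - 1), min(n_beads - 1, i + 2)):
                        a_old = _vertex_angle(
                            pos[c, v - 1, 0], pos[c, v - 1, 1], pos[c, v - 1, 2],
                            pos[c, v, 0], pos[c, v, 1], pos[c, v, 2],
                            pos[c, v + 1, 0], pos[c, v + 1, 1], pos[c, v + 1, 2],
                        )
                        du -= kappa * (a_old - math.pi) ** 2
                    ox, oy, oz = pos[c, i, 0], pos[c, i, 1], pos[c, i, 2]
                    pos[c, i, 0], pos[c, i, 1], pos[c, i, 2] = nx, ny, nz
                    for v in range(max(1, i - 1), min(n_beads - 1, i + 2)):
                        a_new = _vertex_angle(
                            pos[c, v - 1, 0], pos[c, v - 1, 1], pos[c, v - 1, 2],
                            pos[c, v, 0], pos[c, v, 1], pos[c, v, 2],
                            pos[c, v + 1, 0], pos[c, v + 1, 1], pos[c, v + 1, 2],
                        )
                        du += kappa * (a_new - math.pi) ** 2
                    pos[c, i, 0], pos[c, i, 1], pos[c, i, 2] = ox, oy, oz
                if _accept(du):
                    pos[c, i, 0], pos[c, i, 1], pos[c, i, 2] = nx, ny, nz
                    energy += du
                    accepts[0] += 1
            elif t == 4:
                # --- Kawasaki exchange ---------------------------------
                q = marg[m]
                site_a = charged_sites[q]
                site_b = neighbors[site_a, np.random.randint(0, 6)]
                sa, sb = species[site_a], species[site_b]
                if sa == sb:
                    accepts[4] += 1  # identical species: accepted no-op
                    continue
                du = 0.0
                if elec_on:
                    psi_a = _site_potential(
                        site_xy[site_a, 0], site_xy[site_a, 1], site_a, site_b,
                        pos, species, site_xy, charged_sites,
                        static_xyz, static_val, bx, by, periodic, lb, kd, rcut2,
                    )
                    psi_b = _site_potential(
                        site_xy[site_b, 0], site_xy[site_b, 1], site_a, site_b,
                        pos, species, site_xy, charged_sites,
                        static_xyz, static_val, bx, by, periodic, lb, kd, rcut2,
                    )
                    du = (_VAL[sb] - _VAL[sa]) * (psi_a - psi_b)
                if _accept(du):
                    la = site_lipid[site_a]
                    lb_ = site_lipid[site_b]
                    species[site_a], species[site_b] = sb, sa
                    site_lipid[site_a], site_lipid[site_b] = lb_, la
                    if la >= 0:
                        charged_sites[la] = site_b
                    if lb_ >= 0:
                        charged_sites[lb_] = site_a
                    energy += du
                    accepts[4] += 1
            else:
                # --- rigid block moves ---------------------------------
                c = marg[m]
                if t == 1:
                    if n_beads < 3:
                        continue
                    i = np.random.randint(0, n_beads - 2)
                    j = np.random.randint(i + 2, n_beads)
                    lo, hi = i + 1, j
                    ox, oy, oz = pos[c, i, 0], pos[c, i, 1], pos[c, i, 2]
                    ux = pos[c, j, 0] - ox
                    uy = pos[c, j, 1] - oy
                    uz = pos[c, j, 2] - oz
                    un = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux, uy, uz = ux / un, uy / un, uz / un
                    angle = (2.0 * np.random.random() - 1.0) * math.pi
                    for k2 in range(lo, hi):
                        block[k2 - lo, 0], block[k2 - lo, 1], block[k2 - lo, 2] = (
                            _rotate_about_axis(
                                pos[c, k2, 0], pos[c, k2, 1], pos[c, k2, 2],
                                ox, oy, oz, ux, uy, uz, angle,
                            )
                        )
                elif t == 2:
                    lo, hi = 0, n_beads
                    dx = (2.0 * np.random.random() - 1.0) * trans_delta
                    dy = (2.0 * np.random.random() - 1.0) * trans_delta
                    dz = (2.0 * np.random.random() - 1.0) * trans_delta
                    for k2 in range(n_beads):
                        block[k2, 0] = pos[c, k2, 0] + dx
                        block[k2, 1] = pos[c, k2, 1] + dy
                        block[k2, 2] = pos[c, k2, 2] + dz
                else:
                    i = np.random.randint(0, n_beads)
                    if np.random.random() < 0.5:
                        lo, hi = i + 1, n_beads
                    else:
                        lo, hi = 0, i
                    if hi <= lo:
                        accepts[3] += 1  # empty tail: accepted no-op
                        continue
                    ox, oy, oz = pos[c, i, 0], pos[c, i, 1], pos[c, i, 2]
                    ux, uy, uz = _random_unit_vector()
                    angle = (2.0 * np.random.random() - 1.0) * math.pi
                    for k2 in range(lo, hi):
                        block[k2 - lo, 0], block[k2 - lo, 1], block[k2 - lo, 2] = (
                            _rotate_about_axis(
                                pos[c, k2, 0], pos[c, k2, 1], pos[c, k2, 2],
                                ox, oy, oz, ux, uy, uz, angle,
                            )
                        )
                if _block_overlap(pos, c, lo, hi, block, bx, by, periodic, wall):
                    continue
                du = 0.0
                if elec_on:
                    du -= _block_energy(
                        pos, c, lo, hi, pos[c, lo:hi],
                        species, site_xy, charged_sites, static_xyz, static_val,
                        bx, by, periodic, lb, kd, rcut2,
                    )
                    du += _block_energy(
                        pos, c, lo, hi, block[: hi - lo],
                        species, site_xy, charged_sites, static_xyz, static_val,
                        bx, by, periodic, lb, kd, rcut2,
                    )
                if bend_on and kappa > 0.0 and n_beads >= 3:
                    du -= _chain_bend(pos[c], n_beads, kappa)
                    for k2 in range(n_beads):
                        if lo <= k2 < hi:
                            chainbuf[k2, 0] = block[k2 - lo, 0]
                            chainbuf[k2, 1] = block[k2 - lo, 1]
                            chainbuf[k2, 2] = block[k2 - lo, 2]
                        else:
                            chainbuf[k2, 0] = pos[c, k2, 0]
                            chainbuf[k2, 1] = pos[c, k2, 1]
                            chainbuf[k2, 2] = pos[c, k2, 2]
                    du += _chain_bend(chainbuf, n_beads, kappa)
                if _accept(du):
                    for k2 in range(lo, hi):
                        pos[c, k2, 0] = block[k2 - lo, 0]
                        pos[c, k2, 1] = block[k2 - lo, 1]
                        pos[c, k2, 2] = block[k2 - lo, 2]
                    energy += du
                    accepts[t] += 1
                    if t == 2 and periodic:
                        # re-center the chain; all minimum-image distances
                        # are invariant under whole-chain box shifts
                        cx = 0.0
                        cy = 0.0
                        for k2 in range(n_beads):
                            cx += pos[c, k2, 0]
                            cy += pos[c, k2, 1]
                        sx = bx * math.floor(cx / (n_beads * bx))
                        sy = by * math.floor(cy / (n_beads * by))
                        if sx != 0.0 or sy != 0.0:
                            for k2 in range(n_beads):
                                pos[c, k2, 0] -= sx
                                pos[c, k2, 1] -= sy

        wants_frame = record_every > 0 and (step + 1) % record_every == 0
        if wants_frame or (resync_every > 0 and (step + 1) % resync_every == 0):
            full = _total_energy(
                pos, species, site_xy, charged_sites, static_xyz, static_val,
                bx, by, periodic, lb, kd, rcut2, kappa, elec_on, bend_on,
            )
            drift = abs(energy - full)
            if drift > max_drift:
                max_drift = drift
            energy = full
        if wants_frame:
            for c in range(n_chains):
                for i in range(n_beads):
                    rec_pos[n_rec, c, i, 0] = pos[c, i, 0]
                    rec_pos[n_rec, c, i, 1] = pos[c, i, 1]
                    rec_pos[n_rec, c, i, 2] = pos[c, i, 2]
            for s in range(species.shape[0]):
                rec_species[n_rec, s] = species[s]
            for q in range(n_charged):
                rec_lipid_sites[n_rec, q] = charged_sites[q]
            rec_energy[n_rec] = energy
            n_rec += 1

    return n_rec, max_drift, energy
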