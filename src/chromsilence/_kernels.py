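"""Numba kernels: pair lists, forces/energies, Langevin dynamics blocks.

All pair interactions (WCA sterics and weak/strong attractions) are
truncated-and-shifted Lennard-Jones terms selected per particle-type pair
through dense (7, 7) lookup tables: epsilon, squared cutoff and the shift
that makes the energy exactly zero at the cutoff.  A single pair loop
therefore covers bead-bead and TF-TF excluded volume as well as TF-chromatin
attractions.  Bonds (FENE or harmonic) and the Kratky-Porod bending term are
accumulated in separate loops over the chain.

Periodic minimum-image bookkeeping: positions are wrapped into the primary
box only when the Verlet list is rebuilt; between rebuilds particles move by
less than half the skin, so the integer image offset of every listed pair
(and chain bond) is constant and is cached at build time.  The force loops
then use plain coordinate differences minus the cached offsets.

Constraint: summation order is fixed, so a given neighbour-list method is
bitwise deterministic.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BOND_OVERSTRETCH = 1
STATUS_NOT_FINITE = 2
STATUS_PAIR_OVERFLOW = 3

BOND_FENE = 0
BOND_HARMONIC = 1


@njit(cache=True, fastmath=True)
def wrap_in_place(pos, box):
    n = pos.shape[0]
    inv = 1.0 / box
    for i in range(n):
        for d in range(3):
            pos[i, d] -= box * np.floor(pos[i, d] * inv)


@njit(cache=True, fastmath=True)
def build_pairs_allpairs(pos, box, rv2, pair_i, pair_j):
    """All-pairs Verlet-list build; returns pair count or -1 on overflow.

    Positions must already be wrapped into the primary box.
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    inv = 1.0 / box
    m = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx * inv)
            dy -= box * np.rint(dy * inv)
            dz -= box * np.rint(dz * inv)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rv2:
                if m >= cap:
                    return -1
                pair_i[m] = i
                pair_j[m] = j
                m += 1
    return m


@njit(cache=True, fastmath=True)
def build_pairs_cells(pos, box, rv, pair_i, pair_j):
    """Cell-list Verlet build (linked cells); falls back to all-pairs for
    boxes smaller than 3 cells per side.  Returns pair count or -1."""
    n = pos.shape[0]
    ncell = int(box / rv)
    if ncell < 3:
        return build_pairs_allpairs(pos, box, rv * rv, pair_i, pair_j)
    cell_len = box / ncell
    inv_cell = 1.0 / cell_len
    inv = 1.0 / box
    rv2 = rv * rv
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] * inv_cell) % ncell
        iy = int(pos[i, 1] * inv_cell) % ncell
        iz = int(pos[i, 2] * inv_cell) % ncell
        cx[i] = ix
        cy[i] = iy
        cz[i] = iz
        c = (ix * ncell + iy) * ncell + iz
        nxt[i] = head[c]
        head[c] = i
    cap = pair_i.shape[0]
    m = 0
    for i in range(n):
        for ox in range(-1, 2):
            ix = (cx[i] + ox) % ncell
            for oy in range(-1, 2):
                iy = (cy[i] + oy) % ncell
                for oz in range(-1, 2):
                    iz = (cz[i] + oz) % ncell
                    j = head[(ix * ncell + iy) * ncell + iz]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box * np.rint(dx * inv)
                            dy -= box * np.rint(dy * inv)
                            dz -= box * np.rint(dz * inv)
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rv2:
                                if m >= cap:
                                    return -1
                                pair_i[m] = i
                                pair_j[m] = j
                                m += 1
                        j = nxt[j]
    return m


@njit(cache=True, fastmath=True)
def cache_shifts(pos, box, pair_i, pair_j, n_pairs, n_beads, pair_s, bond_s):
    """Cache the periodic image offset of every listed pair and chain bond."""
    inv = 1.0 / box
    for k in range(n_pairs):
        i = pair_i[k]
        j = pair_j[k]
        for d in range(3):
            pair_s[k, d] = box * np.rint((pos[i, d] - pos[j, d]) * inv)
    for i in range(n_beads - 1):
        for d in range(3):
            bond_s[i, d] = box * np.rint((pos[i, d] - pos[i + 1, d]) * inv)


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    code,
    n_beads,
    bond_type,
    bond_k,
    bond_r0,
    kb,
    eps_t,
    rc2_t,
    shift_t,
    pair_i,
    pair_j,
    pair_s,
    bond_s,
    n_pairs,
    forces,
):
    """Accumulate all forces into ``forces``; return (status, total_energy).

    Pair and bond separations use the cached image offsets, so positions may
    be unwrapped by less than half the Verlet skin.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0

    # non-bonded pairs (includes WCA of bonded neighbours, Kremer-Grest style)
    for k in range(n_pairs):
        i = pair_i[k]
        j = pair_j[k]
        dx = pos[i, 0] - pos[j, 0] - pair_s[k, 0]
        dy = pos[i, 1] - pos[j, 1] - pair_s[k, 1]
        dz = pos[i, 2] - pos[j, 2] - pair_s[k, 2]
        r2 = dx * dx + dy * dy + dz * dz
        ci = code[i]
        cj = code[j]
        if r2 < rc2_t[ci, cj]:
            eps = eps_t[ci, cj]
            inv2 = 1.0 / r2
            s6 = inv2 * inv2 * inv2
            s12 = s6 * s6
            energy += 4.0 * eps * (s12 - s6) - shift_t[ci, cj]
            f_over_r = 24.0 * eps * (2.0 * s12 - s6) * inv2
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    # chain bonds
    if bond_type == BOND_FENE:
        r0_2 = bond_r0 * bond_r0
        for i in range(n_beads - 1):
            j = i + 1
            dx = pos[i, 0] - pos[j, 0] - bond_s[i, 0]
            dy = pos[i, 1] - pos[j, 1] - bond_s[i, 1]
            dz = pos[i, 2] - pos[j, 2] - bond_s[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r0_2:
                return STATUS_BOND_OVERSTRETCH, energy
            frac = 1.0 - r2 / r0_2
            energy += -0.5 * bond_k * r0_2 * np.log(frac)
            f_over_r = -bond_k / frac
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    else:
        for i in range(n_beads - 1):
            j = i + 1
            dx = pos[i, 0] - pos[j, 0] - bond_s[i, 0]
            dy = pos[i, 1] - pos[j, 1] - bond_s[i, 1]
            dz = pos[i, 2] - pos[j, 2] - bond_s[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - bond_r0
            energy += 0.5 * bond_k * dr * dr
            f_over_r = -bond_k * dr / r
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    # Kratky-Porod bending on consecutive bond triplets: U = kb * (1 - cos t)
    if kb > 0.0:
        for i in range(n_beads - 2):
            b1x = pos[i + 1, 0] - pos[i, 0] + bond_s[i, 0]
            b1y = pos[i + 1, 1] - pos[i, 1] + bond_s[i, 1]
            b1z = pos[i + 1, 2] - pos[i, 2] + bond_s[i, 2]
            b2x = pos[i + 2, 0] - pos[i + 1, 0] + bond_s[i + 1, 0]
            b2y = pos[i + 2, 1] - pos[i + 1, 1] + bond_s[i + 1, 1]
            b2z = pos[i + 2, 2] - pos[i + 1, 2] + bond_s[i + 1, 2]
            inv_n1 = 1.0 / np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            inv_n2 = 1.0 / np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            e1x = b1x * inv_n1
            e1y = b1y * inv_n1
            e1z = b1z * inv_n1
            e2x = b2x * inv_n2
            e2y = b2y * inv_n2
            e2z = b2z * inv_n2
            c = e1x * e2x + e1y * e2y + e1z * e2z
            energy += kb * (1.0 - c)
            # grad of cos(theta): dc/db1 = (e2 - c e1)/|b1|, dc/db2 = (e1 - c e2)/|b2|
            g1x = (e2x - c * e1x) * inv_n1
            g1y = (e2y - c * e1y) * inv_n1
            g1z = (e2z - c * e1z) * inv_n1
            g2x = (e1x - c * e2x) * inv_n2
            g2y = (e1y - c * e2y) * inv_n2
            g2z = (e1z - c * e2z) * inv_n2
            # F = -dU/dr = kb * dc/dr
            forces[i, 0] += -kb * g1x
            forces[i, 1] += -kb * g1y
            forces[i, 2] += -kb * g1z
            forces[i + 1, 0] += kb * (g1x - g2x)
            forces[i + 1, 1] += kb * (g1y - g2y)
            forces[i + 1, 2] += kb * (g1z - g2z)
            forces[i + 2, 0] += kb * g2x
            forces[i + 2, 1] += kb * g2y
            forces[i + 2, 2] += kb * g2z

    return STATUS_OK, energy


@njit(cache=True, fastmath=True)
def _rebuild(pos, box, rv, use_cells, pair_i, pair_j, n_beads, pair_s, bond_s, ref_pos):
    """Wrap, rebuild the Verlet list, cache image shifts and the reference."""
    wrap_in_place(pos, box)
    if use_cells:
        m = build_pairs_cells(pos, box, rv, pair_i, pair_j)
    else:
        m = build_pairs_allpairs(pos, box, rv * rv, pair_i, pair_j)
    if m < 0:
        return -1
    cache_shifts(pos, box, pair_i, pair_j, m, n_beads, pair_s, bond_s)
    n = pos.shape[0]
    for i in range(n):
        ref_pos[i, 0] = pos[i, 0]
        ref_pos[i, 1] = pos[i, 1]
        ref_pos[i, 2] = pos[i, 2]
    return m


@njit(cache=True, fastmath=True)
def advance_block(
    pos,
    vel,
    code,
    n_beads,
    bond_type,
    bond_k,
    bond_r0,
    kb,
    eps_t,
    rc2_t,
    shift_t,
    box,
    dt,
    gamma,
    kT,
    noise,
    pair_i,
    pair_j,
    pair_s,
    bond_s,
    n_pairs_arr,
    ref_pos,
    rv,
    skin,
    forces,
    use_cells,
    fresh_forces,
):
    """Advance ``noise.shape[0]`` BAOAB Langevin steps in place (unit mass).

    Splitting per step: half kick (B), half drift (A), Ornstein-Uhlenbeck
    velocity refresh (O), half drift (A), force recomputation, half kick
    (B).  ``fresh_forces`` must be non-zero on the first call (or after any
    external change to positions or interaction tables) so the entry-point
    forces are recomputed.  The Verlet pair list is rebuilt (and positions
    wrapped) whenever any particle has moved more than skin/2 since the
    last build; ``n_pairs_arr[0] < 0`` forces a rebuild.  Positions are
    wrapped on exit.  Returns a STATUS_* code.
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    half_dt = 0.5 * dt
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    half_skin2 = 0.25 * skin * skin

    if fresh_forces != 0 or n_pairs_arr[0] < 0:
        m = _rebuild(pos, box, rv, use_cells, pair_i, pair_j, n_beads,
                     pair_s, bond_s, ref_pos)
        if m < 0:
            return STATUS_PAIR_OVERFLOW
        n_pairs_arr[0] = m
        status, _ = compute_forces(
            pos, code, n_beads, bond_type, bond_k, bond_r0, kb,
            eps_t, rc2_t, shift_t, pair_i, pair_j, pair_s, bond_s,
            n_pairs_arr[0], forces,
        )
        if status != STATUS_OK:
            return status

    for b in range(n_steps):
        for i in range(n):
            for d in range(3):
                v = vel[i, d] + half_dt * forces[i, d]
                x = pos[i, d] + half_dt * v
                v = c1 * v + c2 * noise[b, i, d]
                pos[i, d] = x + half_dt * v
                vel[i, d] = v
        need = False
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            if dx * dx + dy * dy + dz * dz > half_skin2:
                need = True
                break
        if need:
            m = _rebuild(pos, box, rv, use_cells, pair_i, pair_j, n_beads,
                         pair_s, bond_s, ref_pos)
            if m < 0:
                return STATUS_PAIR_OVERFLOW
            n_pairs_arr[0] = m
        status, _ = compute_forces(
            pos, code, n_beads, bond_type, bond_k, bond_r0, kb,
            eps_t, rc2_t, shift_t, pair_i, pair_j, pair_s, bond_s,
            n_pairs_arr[0], forces,
        )
        if status != STATUS_OK:
            return status
        for i in range(n):
            vel[i, 0] += half_dt * forces[i, 0]
            vel[i, 1] += half_dt * forces[i, 1]
            vel[i, 2] += half_dt * forces[i, 2]
    wrap_in_place(pos, box)
    if not np.isfinite(pos).all():
        return STATUS_NOT_FINITE
    return STATUS_OK


@njit(cache=True, fastmath=True)
def descend(
    pos, code, n_beads, bond_type, bond_k, bond_r0, kb,
    eps_t, rc2_t, shift_t, box, n_iter, step_size, max_disp,
    pair_i, pair_j, pair_s, bond_s, forces,
):
    """Capped steepest-descent relaxation (removes initial overlaps)."""
    n = pos.shape[0]
    rv = np.sqrt(rc2_t.max()) + 0.3
    ref = np.empty_like(pos)
    for _ in range(n_iter):
        m = _rebuild(pos, box, rv, False, pair_i, pair_j, n_beads,
                     pair_s, bond_s, ref)
        if m < 0:
            return STATUS_PAIR_OVERFLOW
        status, _ = compute_forces(
            pos, code, n_beads, bond_type, bond_k, bond_r0, kb,
            eps_t, rc2_t, shift_t, pair_i, pair_j, pair_s, bond_s, m, forces,
        )
        if status != STATUS_OK and status != STATUS_BOND_OVERSTRETCH:
            return status
        for i in range(n):
            fx = forces[i, 0]
            fy = forces[i, 1]
            fz = forces[i, 2]
            fn = np.sqrt(fx * fx + fy * fy + fz * fz)
            if fn == 0.0:
                continue
            scale = step_size
            if scale * fn > max_disp:
                scale = max_disp / fn
            pos[i, 0] += scale * fx
            pos[i, 1] += scale * fy
            pos[i, 2] += scale * fz
    wrap_in_place(pos, box)
    return STATUS_OK
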