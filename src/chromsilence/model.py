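"""Mechanics of the chromatin + TF system: energies, forces, dynamics.

The polymer is a Kremer-Grest-style bead-spring chain (FENE bonds + WCA
excluded volume) with a Kratky-Porod bending term; transcription factors are
spheres of the same diameter.  Attractive TF-chromatin contacts are
truncated-and-shifted Lennard-Jones wells whose depth is selected by an
:class:`~chromsilence.regulation.InteractionTable`.  Dynamics are Langevin
(BAOAB discretisation, unit mass), so over times long compared with the
inertial time 1/gamma a free particle diffuses with D = kT / gamma.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernels
from ._kernels import (
    BOND_FENE,
    BOND_HARMONIC,
    STATUS_BOND_OVERSTRETCH,
    STATUS_NOT_FINITE,
    STATUS_OK,
    STATUS_PAIR_OVERFLOW,
)
from .core import (
    WCA_CUT,
    Affinity,
    ChromatinState,
    ForceField,
    SystemState,
    min_image_distance,
)

__all__ = [
    "bond_energy",
    "bending_energy",
    "pair_energy",
    "bond_minimum",
    "dense_pair_tables",
    "total_force",
    "total_energy",
    "langevin_step",
    "relax",
    "build_system",
    "IntegrationError",
]

_STATUS_MESSAGES = {
    STATUS_BOND_OVERSTRETCH: "FENE bond reached its maximum extension (chain blow-up)",
    STATUS_NOT_FINITE: "non-finite particle positions (integration instability)",
    STATUS_PAIR_OVERFLOW: "neighbour-list capacity exceeded",
}


class IntegrationError(RuntimeError):
    """Raised when the integrator detects a corrupted configuration."""


# --------------------------------------------------------------------------
# scalar potentials (reference implementations; the kernels mirror them)
# --------------------------------------------------------------------------

def bond_energy(r, ff: ForceField):
    """Spring energy of a chain bond at separation ``r`` (sigma).

    FENE: -0.5 K R0^2 ln(1 - (r/R0)^2), diverging as r -> R0.
    Harmonic: 0.5 k (r - r0)^2.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond separation must be positive")
    if ff.bond_type == "fene":
        if np.any(r >= ff.fene_r0):
            raise ValueError("r >= FENE maximum extension R0 (chain blow-up)")
        x = (r / ff.fene_r0) ** 2
        out = -0.5 * ff.bond_k * ff.fene_r0 ** 2 * np.log1p(-x)
    else:
        out = 0.5 * ff.bond_k * (r - ff.bond_r0) ** 2
    return out if out.shape else float(out)


def bending_energy(theta, kb: float):
    """Kratky-Porod energy ``kb * (1 - cos theta)``; theta=0 is collinear."""
    theta = np.clip(np.asarray(theta, dtype=float), 0.0, np.pi)
    out = kb * (1.0 - np.cos(theta))
    return out if out.shape else float(out)


def _lj(r, eps, cutoff):
    s6 = (1.0 / np.asarray(r, dtype=float)) ** 6
    shift = 4.0 * eps * ((1.0 / cutoff) ** 12 - (1.0 / cutoff) ** 6)
    return np.where(r < cutoff, 4.0 * eps * (s6 * s6 - s6) - shift, 0.0)


def pair_energy(r, affinity: Affinity, ff: ForceField):
    """Non-bonded pair energy at separation ``r`` for a given affinity class.

    STERIC is the WCA potential (eps = 1 kT, cut at 2^(1/6) sigma); WEAK and
    STRONG are truncated-and-shifted Lennard-Jones wells of depth eps_weak /
    eps_strong cut at ``ff.attraction_cutoff``.  Exactly zero at and beyond
    the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    if affinity == Affinity.STERIC:
        out = _lj(r, 1.0, WCA_CUT)
    elif affinity == Affinity.WEAK:
        out = _lj(r, ff.eps_weak, ff.attraction_cutoff)
    else:
        out = _lj(r, ff.eps_strong, ff.attraction_cutoff)
    return out if out.shape else float(out)


def bond_minimum(ff: ForceField) -> float:
    """Separation minimising the combined bond + WCA potential (sigma)."""
    upper = min(WCA_CUT, ff.fene_r0 - 1e-9) if ff.bond_type == "fene" else WCA_CUT

    def u(r):
        return bond_energy(r, ff) + pair_energy(r, Affinity.STERIC, ff)

    res = minimize_scalar(u, bounds=(0.6, upper), method="bounded")
    return float(res.x)


# --------------------------------------------------------------------------
# dense tables and force evaluation
# --------------------------------------------------------------------------

def dense_pair_tables(table, ff: ForceField):
    """Build (7,7) eps / squared-cutoff / shift lookup tables.

    ``table`` is an InteractionTable (or any object with ``as_array()``
    returning the (species, state, chromatin_state) -> Affinity map).
    Bead-bead and TF-TF pairs are always WCA.
    """
    aff = table.as_array()
    eps_t = np.empty((7, 7))
    rc_t = np.empty((7, 7))
    for ci in range(7):
        for cj in range(7):
            if (ci < 3) == (cj < 3):  # bead-bead or TF-TF
                a = Affinity.STERIC
            else:
                bead, tf = (ci, cj) if ci < 3 else (cj, ci)
                species, state = (tf - 3) // 2, (tf - 3) % 2
                a = Affinity(aff[species, state, bead])
            if a == Affinity.STERIC:
                eps_t[ci, cj], rc_t[ci, cj] = 1.0, WCA_CUT
            elif a == Affinity.WEAK:
                eps_t[ci, cj], rc_t[ci, cj] = ff.eps_weak, ff.attraction_cutoff
            else:
                eps_t[ci, cj], rc_t[ci, cj] = ff.eps_strong, ff.attraction_cutoff
    shift_t = 4.0 * eps_t * ((1.0 / rc_t) ** 12 - (1.0 / rc_t) ** 6)
    return eps_t, rc_t ** 2, shift_t


def _bond_params(ff: ForceField):
    if ff.bond_type == "fene":
        return BOND_FENE, ff.bond_k, ff.fene_r0
    return BOND_HARMONIC, ff.bond_k, ff.bond_r0


def _pair_buffers(n: int, n_beads: int):
    cap = max(64 * n, 4096)
    return (
        np.empty(cap, dtype=np.int64),
        np.empty(cap, dtype=np.int64),
        np.zeros((cap, 3)),
        np.zeros((max(n_beads - 1, 1), 3)),
    )


def _forces_and_energy(state: SystemState, table, ff: ForceField, method: str):
    eps_t, rc2_t, shift_t = dense_pair_tables(table, ff)
    code = state.type_codes()
    n = len(code)
    box = state.box_length
    rv = float(np.sqrt(rc2_t.max())) + 1e-9  # no skin for one-shot evaluation
    pair_i, pair_j, pair_s, bond_s = _pair_buffers(n, state.n_beads)
    pos = state.pos.copy()  # rebuild wraps; keep caller's positions intact
    if method == "cells":
        m = _kernels.build_pairs_cells(pos, box, rv, pair_i, pair_j)
    elif method == "allpairs":
        m = _kernels.build_pairs_allpairs(pos, box, rv ** 2, pair_i, pair_j)
    else:
        raise ValueError(f"unknown neighbour method {method!r}")
    if m < 0:
        raise IntegrationError(_STATUS_MESSAGES[STATUS_PAIR_OVERFLOW])
    _kernels.cache_shifts(pos, box, pair_i, pair_j, m, state.n_beads, pair_s, bond_s)
    bond_type, bond_k, bond_r0 = _bond_params(ff)
    forces = np.empty_like(state.pos)
    status, energy = _kernels.compute_forces(
        pos, code, state.n_beads, bond_type, bond_k, bond_r0,
        ff.bending_kb, eps_t, rc2_t, shift_t,
        pair_i, pair_j, pair_s, bond_s, m, forces,
    )
    if status != STATUS_OK:
        raise IntegrationError(_STATUS_MESSAGES[status])
    return forces, energy


def total_force(state: SystemState, table, ff: ForceField, method: str = "cells"):
    """Per-particle force array, minus the gradient of the total energy."""
    return _forces_and_energy(state, table, ff, method)[0]


def total_energy(state: SystemState, table, ff: ForceField, method: str = "cells"):
    """Total potential energy (bonds + bending + all pair terms), kT units."""
    return _forces_and_energy(state, table, ff, method)[1]


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

class LangevinIntegrator:
    """Reusable BAOAB Langevin propagator (unit mass) for one system.

    BAOAB splits each step into half kick / half drift / Ornstein-Uhlenbeck
    velocity refresh / half drift / half kick and samples the configurational
    Boltzmann distribution with small discretisation bias; over times long
    compared with 1/gamma a free particle diffuses with D = kT / gamma.

    Holds the Verlet-list buffers between calls; call :meth:`invalidate`
    after any change to particle types or direct position edits (done
    automatically by :meth:`set_tables`).
    """

    def __init__(
        self,
        state: SystemState,
        ff: ForceField,
        dt: float = 1e-2,
        gamma: float = 1.0,
        kT: float = 1.0,
        skin: float = 0.8,
        method: str = "cells",
    ):
        self.state = state
        self.ff = ff
        self.dt = float(dt)
        self.gamma = float(gamma)
        self.kT = float(kT)
        self.skin = float(skin)
        self.method = method
        n = state.n_beads + state.n_tf
        self._pair_i, self._pair_j, self._pair_s, self._bond_s = _pair_buffers(
            n, state.n_beads
        )
        self._n_pairs = np.array([-1], dtype=np.int64)
        self._ref_pos = np.empty_like(state.pos)
        self._forces = np.empty_like(state.pos)
        self._code = state.type_codes()
        self._tables = None
        self._fresh = True

    def set_tables(self, table) -> None:
        self._tables = dense_pair_tables(table, self.ff)
        self._code = self.state.type_codes()
        self.invalidate()

    def invalidate(self) -> None:
        self._n_pairs[0] = -1
        self._fresh = True

    def run(self, noise: np.ndarray) -> None:
        """Advance ``noise.shape[0]`` steps; noise ~ N(0,1), shape (B, N, 3)."""
        if self._tables is None:
            raise RuntimeError("set_tables() must be called before run()")
        eps_t, rc2_t, shift_t = self._tables
        rv = float(np.sqrt(rc2_t.max())) + self.skin
        bond_type, bond_k, bond_r0 = _bond_params(self.ff)
        status = _kernels.advance_block(
            self.state.pos, self.state.vel, self._code, self.state.n_beads,
            bond_type, bond_k, bond_r0, self.ff.bending_kb,
            eps_t, rc2_t, shift_t, self.state.box_length,
            self.dt, self.gamma, self.kT, noise,
            self._pair_i, self._pair_j, self._pair_s, self._bond_s,
            self._n_pairs, self._ref_pos,
            rv, self.skin, self._forces, self.method == "cells",
            1 if self._fresh else 0,
        )
        if status == STATUS_PAIR_OVERFLOW:
            # grow once and retry from the current configuration
            cap = 2 * len(self._pair_i)
            self._pair_i = np.empty(cap, dtype=np.int64)
            self._pair_j = np.empty(cap, dtype=np.int64)
            self._pair_s = np.zeros((cap, 3))
            self.invalidate()
            return self.run(noise)
        if status != STATUS_OK:
            raise IntegrationError(
                f"{_STATUS_MESSAGES[status]} at step {self.state.step}"
            )
        self._fresh = False
        b = noise.shape[0]
        self.state.step += b
        self.state.time += b * self.dt


def langevin_step(
    state: SystemState,
    table,
    ff: ForceField,
    dt: float,
    gamma: float,
    kT: float,
    rng: np.random.Generator,
    n_steps: int = 1,
    method: str = "cells",
) -> SystemState:
    """Advance ``state`` by ``n_steps`` Langevin (BAOAB) steps in place.

    With all interactions out of range this reduces to free diffusion with
    long-time diffusion constant D = kT / gamma.  Returns the (mutated)
    state for convenience.
    """
    integ = LangevinIntegrator(state, ff, dt=dt, gamma=gamma, kT=kT, method=method)
    integ.set_tables(table)
    n = state.n_beads + state.n_tf
    integ.run(rng.standard_normal((n_steps, n, 3)))
    return state


def relax(
    state: SystemState,
    table,
    ff: ForceField,
    n_iter: int = 200,
    step_size: float = 1e-4,
    max_disp: float = 0.05,
) -> SystemState:
    """Short capped steepest-descent to remove residual build overlaps."""
    eps_t, rc2_t, shift_t = dense_pair_tables(table, ff)
    code = state.type_codes()
    bond_type, bond_k, bond_r0 = _bond_params(ff)
    n = state.n_beads + state.n_tf
    pair_i, pair_j, pair_s, bond_s = _pair_buffers(n, state.n_beads)
    forces = np.empty_like(state.pos)
    status = _kernels.descend(
        state.pos, code, state.n_beads, bond_type, bond_k, bond_r0,
        ff.bending_kb, eps_t, rc2_t, shift_t, state.box_length,
        n_iter, step_size, max_disp, pair_i, pair_j, pair_s, bond_s, forces,
    )
    if status not in (STATUS_OK,):
        raise IntegrationError(_STATUS_MESSAGES[status])
    return state


# --------------------------------------------------------------------------
# system construction
# --------------------------------------------------------------------------

def build_system(
    n_beads: int,
    tu_ids,
    n_active_tf: int,
    n_repressive_tf: int,
    n_on_each: int,
    box_length: float,
    seed,
    ff: ForceField | None = None,
    max_retries: int = 200,
) -> SystemState:
    """Create an initial system: self-avoiding chain + randomly placed TFs.

    ``tu_ids`` are 1-based bead IDs; all TUs start active, exactly
    ``n_on_each`` TFs of each species start ON (chosen at random).  The
    polymer is grown as a self-avoiding random walk with bonds at the
    bond-potential minimum; TFs are inserted uniformly without overlap.

    Raises ValueError for duplicate/out-of-range TU ids, a non-dilute box
    (particle volume fraction >= 1%), or impossible packing.
    """
    ff = ff or ForceField()
    tu_ids = np.asarray(sorted(int(i) for i in tu_ids), dtype=np.int64)
    if len(np.unique(tu_ids)) != len(tu_ids):
        raise ValueError("duplicate TU ids")
    if len(tu_ids) and (tu_ids.min() < 1 or tu_ids.max() > n_beads):
        raise ValueError(f"TU ids must lie in [1, {n_beads}] (1-based)")
    if n_on_each > 0 and (n_on_each > n_active_tf or n_on_each > n_repressive_tf):
        raise ValueError("n_on_each exceeds a TF species count")
    n_tf = n_active_tf + n_repressive_tf
    n_total = n_beads + n_tf
    vol_frac = n_total * (np.pi / 6.0) / box_length ** 3
    if vol_frac >= 0.01:
        raise ValueError(
            f"box not dilute: particle volume fraction {vol_frac:.3f} >= 1%"
        )

    rng = np.random.default_rng(seed)
    b0 = bond_minimum(ff) if n_beads > 1 else 1.0
    hard_core = 0.8  # sigma; relaxation removes residual softness

    pos = np.empty((n_total, 3))
    pos[0] = rng.uniform(0.0, box_length, 3)
    i = 1
    stalls = 0
    while i < n_beads:
        placed = False
        for _ in range(max_retries):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = (pos[i - 1] + b0 * v) % box_length
            d = min_image_distance(pos[:i], cand, box_length)
            if np.all(d[: i - 1] > hard_core) if i > 1 else True:
                pos[i] = cand
                placed = True
                break
        if placed:
            i += 1
        else:  # backtrack a few beads and retry the local growth
            stalls += 1
            if stalls > max_retries:
                raise ValueError("impossible packing: self-avoiding walk stalled")
            i = max(1, i - 10)

    for k in range(n_tf):
        j = n_beads + k
        for attempt in range(max_retries + 1):
            cand = rng.uniform(0.0, box_length, 3)
            d = min_image_distance(pos[:j], cand, box_length)
            if np.all(d > 0.9):
                pos[j] = cand
                break
            if attempt == max_retries:
                raise ValueError("impossible packing: could not insert TFs")

    is_tu = np.zeros(n_beads, dtype=bool)
    is_tu[tu_ids - 1] = True
    chromatin_state = np.where(is_tu, ChromatinState.TU_ACTIVE, ChromatinState.NS)
    tf_species = np.concatenate(
        [np.zeros(n_active_tf, dtype=np.int8), np.ones(n_repressive_tf, dtype=np.int8)]
    )
    tf_state = np.zeros(n_tf, dtype=np.int8)
    if n_active_tf:
        tf_state[rng.choice(n_active_tf, size=n_on_each, replace=False)] = 1
    if n_repressive_tf:
        tf_state[n_active_tf + rng.choice(n_repressive_tf, size=n_on_each, replace=False)] = 1

    return SystemState(
        pos=pos,
        n_beads=n_beads,
        is_tu=is_tu,
        chromatin_state=chromatin_state.astype(np.int8),
        recovery_deadline=np.full(n_beads, -1, dtype=np.int64),
        tf_species=tf_species,
        tf_state=tf_state,
        box_length=float(box_length),
    )
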