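"""Regulatory layer: feedback affinity tables, TF switching, silencing.

Three silencing feedback mechanisms differ only in how repressive ON TFs
interact with chromatin:

* positive ("colour and stick"): strong attraction to both active and
  repressed TUs, weak to unmarked chromatin;
* negative ("colour and flee"): strong attraction to active TUs only,
  purely steric otherwise;
* neutral ("colour and linger"): weak attraction to the whole fibre.

Active ON TFs are identical across feedbacks (strong to active TUs, weak to
repressed TUs and unmarked chromatin); OFF TFs of either species are always
purely steric.

Silencing: a repressive ON TF bound to an active TU (within ``r_bind``)
converts it to the repressed state with probability ``p_s`` per attempt;
the TU reverts deterministically after ``tau_r`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    WCA_CUT,
    Affinity,
    ChromatinState,
    Feedback,
    Species,
    SystemState,
    TFState,
    min_image,
)

__all__ = [
    "InteractionTable",
    "KineticParams",
    "RegulatoryEvent",
    "make_interaction_table",
    "switch_states",
    "bound_tfs",
    "attempt_silencing",
    "process_recovery",
]


@dataclass(frozen=True)
class InteractionTable:
    """Complete affinity map (species, ON/OFF state, chromatin state) -> class."""

    feedback: Feedback
    affinity: dict

    def __getitem__(self, key) -> Affinity:
        species, state, chrom = key
        return self.affinity[(Species(species), TFState(state), ChromatinState(chrom))]

    def as_array(self) -> np.ndarray:
        """(2, 2, 3) int8 array indexed [species, state, chromatin_state]."""
        out = np.empty((2, 2, 3), dtype=np.int8)
        for sp in Species:
            for st in TFState:
                for ch in ChromatinState:
                    out[sp, st, ch] = self.affinity[(sp, st, ch)]
        return out


#: repressive-ON affinities per feedback: (NS, TU_ACTIVE, TU_REPRESSED)
_REPRESSIVE_ON_ROWS = {
    Feedback.POSITIVE: (Affinity.WEAK, Affinity.STRONG, Affinity.STRONG),
    Feedback.NEGATIVE: (Affinity.STERIC, Affinity.STRONG, Affinity.STERIC),
    Feedback.NEUTRAL: (Affinity.WEAK, Affinity.WEAK, Affinity.WEAK),
}


def make_interaction_table(feedback) -> InteractionTable:
    """Affinity table for one of the three silencing feedback mechanisms."""
    feedback = Feedback(feedback)
    aff: dict = {}
    for sp in Species:
        for ch in ChromatinState:
            aff[(sp, TFState.OFF, ch)] = Affinity.STERIC  # OFF is always steric
    # active ON TFs: identical across feedbacks
    aff[(Species.ACTIVE, TFState.ON, ChromatinState.NS)] = Affinity.WEAK
    aff[(Species.ACTIVE, TFState.ON, ChromatinState.TU_ACTIVE)] = Affinity.STRONG
    aff[(Species.ACTIVE, TFState.ON, ChromatinState.TU_REPRESSED)] = Affinity.WEAK
    row = _REPRESSIVE_ON_ROWS[feedback]
    for ch, a in zip(ChromatinState, row):
        aff[(Species.REPRESSIVE, TFState.ON, ch)] = a
    return InteractionTable(feedback=feedback, affinity=aff)


@dataclass(frozen=True)
class KineticParams:
    """Stochastic regulation parameters.

    Cadences and ``tau_r`` are in integration steps; the symmetric switching
    rates are alpha_on = alpha_off = p_switch / switch_interval.
    """

    p_switch: float = 0.002  # flip probability per attempt
    switch_interval: int = 100  # steps between switching attempts
    p_s: float = 1e-3  # silencing probability per attempt
    silencing_interval: int = 100  # steps between silencing attempts
    tau_r: int = 50_000  # repression duration, steps (500 switch intervals)
    r_bind: float = 1.8  # binding-distance cutoff, sigma
    compound_occupancy: bool = False  # p_s compounds over bound repressors

    def __post_init__(self):
        for name in ("p_switch", "p_s"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")
        if self.r_bind < WCA_CUT:
            raise ValueError("r_bind must be at least the steric diameter 2^(1/6)")


@dataclass(frozen=True)
class RegulatoryEvent:
    step: int
    time: float
    tu_id: int  # 1-based bead ID
    kind: str  # "SILENCE" | "RECOVER"


def switch_states(state: SystemState, p_switch: float, rng: np.random.Generator):
    """Flip each TF ON<->OFF independently with probability ``p_switch``.

    One uniform draw per TF, in TF index order.  Mutates and returns
    ``state``.
    """
    if state.n_tf:
        flips = rng.random(state.n_tf) < p_switch
        state.tf_state[flips] ^= 1
    return state


def bound_tfs(
    state: SystemState,
    tu_id: int,
    r_bind: float,
    species=None,
    tf_state=None,
) -> np.ndarray:
    """IDs of TFs within ``r_bind`` (closed boundary) of TU bead ``tu_id``.

    ``tu_id`` is 1-based; optional filters restrict species and ON/OFF state.
    """
    idx = int(tu_id) - 1
    if idx < 0 or idx >= state.n_beads or not state.is_tu[idx]:
        raise ValueError(f"bead {tu_id} is not a TU")
    if state.n_tf == 0:
        return np.empty(0, dtype=np.int64)
    d = min_image(state.tf_pos - state.pos[idx], state.box_length)
    within = np.einsum("ij,ij->i", d, d) <= r_bind * r_bind
    if species is not None:
        within &= state.tf_species == int(species)
    if tf_state is not None:
        within &= state.tf_state == int(tf_state)
    return np.flatnonzero(within)


def _bound_matrix(state: SystemState, tu_idx: np.ndarray, mask: np.ndarray, r_bind: float):
    """(n_tu,) counts of masked TFs within r_bind of each listed TU bead."""
    if not mask.any() or len(tu_idx) == 0:
        return np.zeros(len(tu_idx), dtype=np.int64)
    p = state.tf_pos[mask]
    d = min_image(state.pos[tu_idx][:, None, :] - p[None, :, :], state.box_length)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    return (r2 <= r_bind * r_bind).sum(axis=1)


def attempt_silencing(
    state: SystemState,
    kp: KineticParams,
    rng: np.random.Generator,
    log: list | None = None,
):
    """One silencing attempt over all active TUs (call every
    ``silencing_interval`` steps).

    Each TU_ACTIVE bead with at least one repressive ON TF within
    ``r_bind`` becomes TU_REPRESSED with probability ``p_s`` (or
    ``1-(1-p_s)^m`` over ``m`` bound repressors when
    ``compound_occupancy``); its recovery deadline is set to
    ``step + tau_r``.  At most one state change per TU per attempt.
    Uniform draws are made per eligible TU in ascending bead order.
    """
    tu_idx = state.tu_indices
    active = tu_idx[state.chromatin_state[tu_idx] == ChromatinState.TU_ACTIVE]
    if len(active) == 0:
        return state
    rep_on = (state.tf_species == Species.REPRESSIVE) & (state.tf_state == TFState.ON)
    counts = _bound_matrix(state, active, rep_on, kp.r_bind)
    eligible = active[counts > 0]
    if len(eligible) == 0:
        return state
    if kp.compound_occupancy:
        m = counts[counts > 0].astype(float)
        p = 1.0 - (1.0 - kp.p_s) ** m
    else:
        p = np.full(len(eligible), kp.p_s)
    hit = rng.random(len(eligible)) < p
    silenced = eligible[hit]
    state.chromatin_state[silenced] = ChromatinState.TU_REPRESSED
    state.recovery_deadline[silenced] = state.step + kp.tau_r
    if log is not None:
        for i in silenced:
            log.append(RegulatoryEvent(state.step, state.time, int(i) + 1, "SILENCE"))
    return state


def process_recovery(state: SystemState, log: list | None = None):
    """Reactivate every repressed TU whose deadline has passed (<= now)."""
    due = (state.chromatin_state == ChromatinState.TU_REPRESSED) & (
        state.recovery_deadline >= 0
    ) & (state.recovery_deadline <= state.step)
    idx = np.flatnonzero(due)
    state.chromatin_state[idx] = ChromatinState.TU_ACTIVE
    state.recovery_deadline[idx] = -1
    if log is not None:
        for i in idx:
            log.append(RegulatoryEvent(state.step, state.time, int(i) + 1, "RECOVER"))
    return state
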