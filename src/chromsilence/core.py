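"""Domain types for the chromatin-fibre / transcription-factor model.

The system is a bead-spring chromatin polymer (bead diameter ``sigma``, the
simulation length unit, physically ~20-30 nm or 1-3 kbp per bead) plus a set
of diffusing multivalent transcription-factor (TF) spheres in a periodic
cubic box.  Beads are either non-specific chromatin (NS) or transcription
units (TUs); a TU is permanently a TU but toggles between an active and a
repressed chromatin state.  TFs come in two species (active / repressive)
and stochastically switch between an interacting ON state and a purely
steric OFF state.

Energies are in units of k_BT, lengths in sigma, and time in Brownian times
tau_B = sigma^2 * gamma / k_BT.  Regulatory bookkeeping (switching cadence,
recovery deadlines) is denominated in integer integration steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np

#: WCA (purely repulsive truncated-shifted Lennard-Jones) cutoff, sigma units.
WCA_CUT: float = 2.0 ** (1.0 / 6.0)


class ChromatinState(IntEnum):
    NS = 0
    TU_ACTIVE = 1
    TU_REPRESSED = 2


class Species(IntEnum):
    ACTIVE = 0
    REPRESSIVE = 1


class TFState(IntEnum):
    OFF = 0
    ON = 1


class Affinity(IntEnum):
    STERIC = 0
    WEAK = 1
    STRONG = 2


class Feedback(str, Enum):
    """Silencing feedback mechanism (repressive-TF affinity rule).

    POSITIVE ("colour and stick"): repressors stay strongly bound to the TUs
    they silenced.  NEGATIVE ("colour and flee"): repressors bind strongly
    only to active TUs and detach after silencing.  NEUTRAL ("colour and
    linger"): repressors are weakly attracted to all chromatin.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


# Dense per-particle type codes used by the force kernels and trajectory I/O.
# Beads carry their chromatin state (0..2); TFs are 3 + 2*species + state.
CODE_NS = 0
CODE_TU_ACTIVE = 1
CODE_TU_REPRESSED = 2
CODE_TF_ACTIVE_OFF = 3
CODE_TF_ACTIVE_ON = 4
CODE_TF_REPRESSIVE_OFF = 5
CODE_TF_REPRESSIVE_ON = 6

CODE_NAMES = {
    CODE_NS: "NS",
    CODE_TU_ACTIVE: "TU_ACTIVE",
    CODE_TU_REPRESSED: "TU_REPRESSED",
    CODE_TF_ACTIVE_OFF: "TF_ACTIVE_OFF",
    CODE_TF_ACTIVE_ON: "TF_ACTIVE_ON",
    CODE_TF_REPRESSIVE_OFF: "TF_REPRESSIVE_OFF",
    CODE_TF_REPRESSIVE_ON: "TF_REPRESSIVE_ON",
}
NAME_CODES = {v: k for k, v in CODE_NAMES.items()}


def tf_code(species: int, state: int) -> int:
    """Dense type code of a TF with the given species and ON/OFF state."""
    return 3 + 2 * int(species) + int(state)


@dataclass(frozen=True)
class ForceField:
    """Mechanical force-field parameters (energies in k_BT, lengths in sigma).

    Bonds are finitely extensible (FENE) springs by default, combined with
    WCA excluded volume as in the Kremer-Grest polymer model; a harmonic
    option is provided.  A Kratky-Porod term ``kb * (1 - cos theta)`` on
    consecutive bond triplets sets the persistence length.  Attractive
    TF-chromatin contacts are truncated-and-shifted Lennard-Jones wells of
    depth ``eps_weak`` or ``eps_strong`` cut at ``attraction_cutoff``.
    """

    bond_type: str = "fene"  # "fene" | "harmonic"
    bond_k: float = 30.0  # spring constant, kT/sigma^2
    fene_r0: float = 1.6  # FENE maximum extension, sigma
    bond_r0: float = 1.0  # harmonic rest length, sigma
    bending_kb: float = 3.0  # Kratky-Porod constant, kT
    eps_weak: float = 3.0
    eps_strong: float = 8.0
    attraction_cutoff: float = 1.8

    def __post_init__(self) -> None:
        if self.bond_type not in ("fene", "harmonic"):
            raise ValueError(f"unknown bond_type {self.bond_type!r}")
        if not (self.eps_strong > self.eps_weak > 0):
            raise ValueError("require eps_strong > eps_weak > 0")
        if not self.attraction_cutoff > WCA_CUT:
            raise ValueError("attraction_cutoff must exceed the WCA cutoff 2^(1/6)")


@dataclass
class Bead:
    """A chromatin monomer (inspection view; the hot path uses arrays).

    ``id`` is 0-based internally; all user-facing output is 1-based.
    """

    id: int
    position: np.ndarray
    chromatin_state: ChromatinState
    is_tu: bool
    recovery_deadline: int | None  # integration step, None when not repressed


@dataclass
class TFParticle:
    """A diffusing multivalent transcription-factor sphere."""

    id: int
    position: np.ndarray
    species: Species
    state: TFState


@dataclass
class SystemState:
    """Complete mechanical + regulatory state of one simulation.

    Positions of all particles (beads first, then TFs) live in a single
    ``(n_beads + n_tf, 3)`` array wrapped into the primary periodic box.
    """

    pos: np.ndarray  # (N, 3) float64, sigma units
    n_beads: int
    is_tu: np.ndarray  # (n_beads,) bool
    chromatin_state: np.ndarray  # (n_beads,) int8
    recovery_deadline: np.ndarray  # (n_beads,) int64, -1 == none
    tf_species: np.ndarray  # (n_tf,) int8
    tf_state: np.ndarray  # (n_tf,) int8
    box_length: float
    step: int = 0
    time: float = 0.0
    vel: np.ndarray | None = None  # (N, 3); zeros when not thermalised

    def __post_init__(self) -> None:
        if self.vel is None:
            self.vel = np.zeros_like(self.pos)

    # -- derived views ----------------------------------------------------
    @property
    def n_tf(self) -> int:
        return len(self.tf_species)

    @property
    def bead_pos(self) -> np.ndarray:
        return self.pos[: self.n_beads]

    @property
    def tf_pos(self) -> np.ndarray:
        return self.pos[self.n_beads:]

    @property
    def tu_indices(self) -> np.ndarray:
        """0-based bead indices of the transcription units, ascending."""
        return np.flatnonzero(self.is_tu)

    @property
    def tu_ids(self) -> np.ndarray:
        """1-based TU bead IDs as used in all outputs."""
        return self.tu_indices + 1

    @property
    def beads(self) -> list[Bead]:
        return [
            Bead(
                id=i,
                position=self.pos[i].copy(),
                chromatin_state=ChromatinState(int(self.chromatin_state[i])),
                is_tu=bool(self.is_tu[i]),
                recovery_deadline=(
                    int(self.recovery_deadline[i])
                    if self.recovery_deadline[i] >= 0
                    else None
                ),
            )
            for i in range(self.n_beads)
        ]

    @property
    def tfs(self) -> list[TFParticle]:
        return [
            TFParticle(
                id=i,
                position=self.pos[self.n_beads + i].copy(),
                species=Species(int(self.tf_species[i])),
                state=TFState(int(self.tf_state[i])),
            )
            for i in range(self.n_tf)
        ]

    def type_codes(self) -> np.ndarray:
        """Dense per-particle type codes (beads then TFs), int64."""
        codes = np.empty(self.n_beads + self.n_tf, dtype=np.int64)
        codes[: self.n_beads] = self.chromatin_state
        codes[self.n_beads:] = 3 + 2 * self.tf_species.astype(np.int64) + self.tf_state
        return codes

    def copy(self) -> "SystemState":
        return SystemState(
            pos=self.pos.copy(),
            n_beads=self.n_beads,
            is_tu=self.is_tu.copy(),
            chromatin_state=self.chromatin_state.copy(),
            recovery_deadline=self.recovery_deadline.copy(),
            tf_species=self.tf_species.copy(),
            tf_state=self.tf_state.copy(),
            box_length=self.box_length,
            step=self.step,
            time=self.time,
            vel=self.vel.copy(),
        )

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.pos.shape != (self.n_beads + self.n_tf, 3):
            raise ValueError("position array shape inconsistent with particle counts")
        if not np.isfinite(self.pos).all():
            raise ValueError("non-finite particle positions")
        if np.any((self.chromatin_state != ChromatinState.NS) & ~self.is_tu):
            raise ValueError("non-TU bead with a TU chromatin state")
        repressed = self.chromatin_state == ChromatinState.TU_REPRESSED
        if np.any(repressed & (self.recovery_deadline < 0)):
            raise ValueError("repressed TU without a recovery deadline")
        if np.any(~repressed & (self.recovery_deadline >= 0)):
            raise ValueError("recovery deadline on a non-repressed bead")


def min_image(d: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image displacement(s) for a cubic periodic box."""
    return d - box * np.round(d / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image Euclidean distance between positions ``a`` and ``b``."""
    d = min_image(np.asarray(a) - np.asarray(b), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_positions(pos: np.ndarray, box: float) -> np.ndarray:
    """Wrap positions into the primary box [0, box)."""
    return pos - box * np.floor(pos / box)
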