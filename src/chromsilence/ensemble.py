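"""Replica runner, seeded ensembles, p_s scans and the silencing transition.

A replica is one full simulation: build, steepest-descent relaxation, then
Langevin dynamics with regulatory events (recovery, ON/OFF switching,
silencing attempts) interleaved at their step cadences.  Ensembles derive
independent replica seeds reproducibly from a base seed; a scan runs one
ensemble per silencing probability and the transition locator finds where
the activity curve crosses the midpoint between its low- and high-p_s
plateaus (log-interpolated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .core import SystemState
from .model import LangevinIntegrator, build_system, relax
from .observables import (
    TUCode,
    active_tf_partition,
    boomerang_stats,
    frame_tu_codes,
    mean_active_cluster_size,
)
from .regulation import (
    RegulatoryEvent,
    attempt_silencing,
    make_interaction_table,
    process_recovery,
    switch_states,
)

__all__ = [
    "ReplicaResult",
    "EnsembleResult",
    "ScanResult",
    "TransitionEstimate",
    "replica_seed",
    "run_replica",
    "run_ensemble",
    "scan_ps",
    "locate_transition",
    "bootstrap_transition",
]

#: version tag for the documented RNG draw order (thermal noise block, then
#: recovery [no draws], switching [one uniform per TF], silencing [one
#: uniform per eligible TU in ascending bead order]).
RNG_ORDER_VERSION = "rng-order-1"


@dataclass
class ReplicaResult:
    """Per-frame records and derived quantities of one replica."""

    seed: int
    feedback: str
    p_s: float
    tu_ids: np.ndarray  # 1-based
    frame_steps: np.ndarray  # (F,)
    frame_times: np.ndarray  # (F,)
    tu_codes: np.ndarray  # (F, n_tu) int8, TUCode values
    active_cluster_size: np.ndarray  # (F,) mean size of active-TF clusters
    events: list
    n_equil_frames: int  # frames discarded as equilibration

    @property
    def used(self) -> slice:
        return slice(self.n_equil_frames, None)

    @property
    def activities(self) -> np.ndarray:
        """Per-TU activity: fraction of post-equilibration frames transcribing."""
        codes = self.tu_codes[self.used]
        if len(codes) == 0:
            raise ValueError("no frames after the equilibration window")
        return (codes == TUCode.ON_TRANSCRIBING).mean(axis=0)

    @property
    def mean_cluster_size(self) -> float:
        """Time-averaged active-TF cluster size (post-equilibration)."""
        return float(self.active_cluster_size[self.used].mean())


def run_replica(
    config: SimulationConfig,
    seed: int,
    keep_frames: bool = False,
) -> ReplicaResult:
    """Run the full pipeline for one replica; deterministic given ``seed``.

    When ``keep_frames`` is true the returned object grows a ``frames``
    attribute with a deep-copied :class:`SystemState` per recorded frame
    (memory-heavy; meant for small systems and trajectory output).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    tu_ids = config.resolve_tu_ids()
    state = build_system(
        n_beads=config.fibre.n_beads,
        tu_ids=tu_ids,
        n_active_tf=config.tfs.n_active,
        n_repressive_tf=config.tfs.n_repressive,
        n_on_each=config.tfs.n_on_each,
        box_length=config.fibre.box_length,
        seed=rng,
        ff=config.forcefield,
    )
    table = make_interaction_table(config.feedback)
    relax(state, table, config.forcefield, n_iter=config.integrator.relax_iter)

    integ = LangevinIntegrator(
        state,
        config.forcefield,
        dt=config.integrator.dt,
        gamma=config.integrator.gamma,
        kT=config.integrator.kT,
        skin=config.integrator.neighbor_skin,
        method=config.integrator.neighbor_method,
    )
    integ.set_tables(table)

    kin = config.kinetics
    steps = config.integrator.steps
    stride = config.sampling.stride
    n = state.n_beads + state.n_tf
    # regulatory attempts and sampling share a common block cadence
    block = math.gcd(math.gcd(kin.switch_interval, kin.silencing_interval), stride)
    events: list[RegulatoryEvent] = []
    frames: list[SystemState] = []
    frame_steps, frame_times, codes, csize = [], [], [], []

    def record() -> None:
        frame_steps.append(state.step)
        frame_times.append(state.time)
        codes.append(frame_tu_codes(state, kin.r_bind))
        part = active_tf_partition(
            state, config.observables.r_clust, config.observables.cluster_on_only
        )
        csize.append(
            mean_active_cluster_size([part], config.observables.min_cluster_size)[0]
        )
        if keep_frames:
            frames.append(state.copy())

    record()  # initial frame at t=0
    for _ in range(steps // block):
        integ.run(rng.standard_normal((block, n, 3), dtype=np.float32))
        changed = False
        if state.step % kin.silencing_interval == 0:
            before = state.chromatin_state.copy()
            process_recovery(state, log=events)
            changed |= bool((before != state.chromatin_state).any())
        if state.step % kin.switch_interval == 0:
            before_tf = state.tf_state.copy()
            switch_states(state, kin.p_switch, rng)
            changed |= bool((before_tf != state.tf_state).any())
        if state.step % kin.silencing_interval == 0:
            before = state.chromatin_state.copy()
            attempt_silencing(state, kin, rng, log=events)
            changed |= bool((before != state.chromatin_state).any())
        if changed:
            integ.set_tables(table)
        if state.step % stride == 0:
            record()

    n_frames = len(frame_steps)
    n_equil = int(np.ceil(config.sampling.equilibration_fraction * n_frames))
    result = ReplicaResult(
        seed=int(seed),
        feedback=config.feedback.value,
        p_s=kin.p_s,
        tu_ids=tu_ids,
        frame_steps=np.asarray(frame_steps, dtype=np.int64),
        frame_times=np.asarray(frame_times, dtype=float),
        tu_codes=np.stack(codes) if codes else np.empty((0, len(tu_ids)), np.int8),
        active_cluster_size=np.asarray(csize, dtype=float),
        events=events,
        n_equil_frames=n_equil,
    )
    if keep_frames:
        result.frames = frames  # type: ignore[attr-defined]
    return result


def replica_seed(base_seed: int, *key: int) -> int:
    """Deterministic, collision-resistant sub-seed (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class EnsembleResult:
    """Aggregated records of independent replicas at one parameter point."""

    config: SimulationConfig
    replicas: list
    base_seed: int

    @property
    def activities(self) -> np.ndarray:
        """(n_tu, n_replicas) per-replica time-averaged activities."""
        return np.stack([r.activities for r in self.replicas], axis=1)

    @property
    def mean_activity(self) -> float:
        """<a>: mean over TUs of the replica-averaged per-TU activity."""
        return float(self.activities.mean(axis=1).mean())

    @property
    def sem_activity(self) -> float:
        per_rep = self.activities.mean(axis=0)
        if len(per_rep) < 2:
            return float("nan")
        return float(per_rep.std(ddof=1) / np.sqrt(len(per_rep)))

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Per-replica time-averaged active-TF cluster size."""
        return np.array([r.mean_cluster_size for r in self.replicas])

    def boomerang(self, noise_metric: str = "sd"):
        return boomerang_stats(
            self.activities, tu_ids=self.replicas[0].tu_ids, noise_metric=noise_metric
        )


def run_ensemble(
    config: SimulationConfig,
    n_replicas: int,
    base_seed: int,
    n_jobs: int = 1,
) -> EnsembleResult:
    """Run ``n_replicas`` independent replicas with derived seeds.

    Results are identical for serial and parallel execution because each
    replica owns a seed derived only from (base_seed, replica index).
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    seeds = [replica_seed(base_seed, k) for k in range(n_replicas)]
    if n_jobs == 1:
        replicas = [run_replica(config, s) for s in seeds]
    else:
        from joblib import Parallel, delayed

        replicas = Parallel(n_jobs=n_jobs)(
            delayed(run_replica)(config, s) for s in seeds
        )
    return EnsembleResult(config=config, replicas=list(replicas), base_seed=base_seed)


@dataclass
class ScanResult:
    """Activity (and companions) across a silencing-probability grid."""

    feedback: str
    ps_grid: np.ndarray
    n_replicas: int
    ensembles: list

    def __post_init__(self):
        ps = np.asarray(self.ps_grid, dtype=float)
        if np.any(np.diff(ps) <= 0):
            raise ValueError("ps_grid must be strictly increasing")
        self.ps_grid = ps

    @property
    def mean_activity(self) -> np.ndarray:
        return np.array([e.mean_activity for e in self.ensembles])

    @property
    def sem_activity(self) -> np.ndarray:
        return np.array([e.sem_activity for e in self.ensembles])

    @property
    def mean_noise(self) -> np.ndarray:
        """Mean over TUs of sigma_a,TU at each grid point."""
        return np.array(
            [float(e.boomerang()["sigma_a_tu"].mean()) for e in self.ensembles]
        )

    @property
    def mean_cluster_size(self) -> np.ndarray:
        return np.array([float(e.cluster_sizes.mean()) for e in self.ensembles])


def scan_ps(
    config: SimulationConfig,
    ps_grid,
    n_replicas: int,
    base_seed: int,
    n_jobs: int = 1,
) -> ScanResult:
    """One ensemble per grid point; all non-p_s parameters identical.

    Replica seeds are shared across grid points (common random numbers):
    replica ``k`` uses the same thermal/regulatory noise stream at every
    p_s, so differences along the curve reflect the silencing probability
    rather than independent sampling noise.  Replicas within an ensemble
    remain mutually independent, and comparisons across grid points can be
    paired by replica index.
    """
    ps_grid = np.asarray(sorted(float(p) for p in ps_grid))
    if np.any(ps_grid < 0) or np.any(ps_grid > 1):
        raise ValueError("ps_grid values must be probabilities")
    seeds = [replica_seed(base_seed, k) for k in range(n_replicas)]
    ensembles = []
    for ps in ps_grid:
        cfg = config.with_ps(ps)
        if n_jobs == 1:
            replicas = [run_replica(cfg, s) for s in seeds]
        else:
            from joblib import Parallel, delayed

            replicas = Parallel(n_jobs=n_jobs)(
                delayed(run_replica)(cfg, s) for s in seeds
            )
        ensembles.append(
            EnsembleResult(config=cfg, replicas=list(replicas), base_seed=base_seed)
        )
    return ScanResult(
        feedback=config.feedback.value,
        ps_grid=ps_grid,
        n_replicas=n_replicas,
        ensembles=ensembles,
    )


@dataclass
class TransitionEstimate:
    """Midpoint-crossing estimate of the silencing transition."""

    ps_critical: float  # nan when no transition is detected
    plateau_low: float
    plateau_high: float
    method: str = "midpoint_crossing"

    @property
    def found(self) -> bool:
        return np.isfinite(self.ps_critical)


def _locate(ps: np.ndarray, act: np.ndarray) -> TransitionEstimate:
    low = act[ps < ps.min() * 10.0]
    high = act[ps > ps.max() / 10.0]
    plateau_low = float(low.mean())
    plateau_high = float(high.mean())
    if plateau_low <= plateau_high:
        return TransitionEstimate(float("nan"), plateau_low, plateau_high)
    mid = 0.5 * (plateau_low + plateau_high)
    below = np.flatnonzero(act < mid)
    if len(below) == 0 or below[0] == 0:
        return TransitionEstimate(float("nan"), plateau_low, plateau_high)
    j = below[0]
    x1, x2 = np.log10(ps[j - 1]), np.log10(ps[j])
    y1, y2 = act[j - 1], act[j]
    x = x1 + (mid - y1) / (y2 - y1) * (x2 - x1)
    return TransitionEstimate(float(10.0 ** x), plateau_low, plateau_high)


def locate_transition(scan: ScanResult) -> TransitionEstimate:
    """Locate the silencing transition on a (log-spaced) p_s grid.

    The low/high plateaus are the mean activities over the lowest and
    highest scanned decades; ps_critical is the log-interpolated crossing
    of their midpoint.  A flat or non-decreasing curve yields a
    no-transition estimate (ps_critical = nan), not an exception.
    Invariant under monotone (affine) rescaling of the activity axis.
    """
    if len(scan.ps_grid) < 4:
        raise ValueError("need at least 4 grid points")
    return _locate(scan.ps_grid, scan.mean_activity)


def bootstrap_transition(
    scan: ScanResult,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
):
    """Bootstrap (over replicas) confidence interval on ps_critical.

    Returns (lo, hi) percentiles of the finite bootstrap estimates; nan
    bounds when fewer than half the resamples locate a transition.
    """
    rng = np.random.default_rng(seed)
    acts = [e.activities for e in scan.ensembles]  # (n_tu, n_rep) each
    n_rep = acts[0].shape[1]
    estimates = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_rep, size=n_rep)
        curve = np.array([a[:, pick].mean(axis=1).mean() for a in acts])
        estimates.append(_locate(scan.ps_grid, curve).ps_critical)
    est = np.asarray(estimates, dtype=float)
    finite = est[np.isfinite(est)]
    if len(finite) < n_boot / 2:
        return float("nan"), float("nan")
    alpha = (1.0 - ci) / 2.0
    return (
        float(np.quantile(finite, alpha)),
        float(np.quantile(finite, 1.0 - alpha)),
    )
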