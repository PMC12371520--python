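"""Derived quantities: TU activity, kymographs, TF clusters, noise, networks.

Activity of a TU is the fraction of sampled frames in which the TU is in
the active chromatin state *and* has at least one active ON TF within the
binding range — a proxy for the transcription rate.  Averaging is two-stage:
first over replicas per TU (<a_TU>), then over TUs (<a>).  Transcriptional
noise sigma_a,TU is the dispersion of a TU's (time-averaged) activity across
independent replicas, a cell-to-cell variability proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import networkx as nx
import numpy as np
import pandas as pd

from .core import Species, SystemState, TFState, ChromatinState, min_image

__all__ = [
    "TUCode",
    "ClusterPartition",
    "CorrelationNetwork",
    "tu_activity",
    "kymograph",
    "frame_tu_codes",
    "detect_clusters",
    "mean_active_cluster_size",
    "boomerang_stats",
    "correlation_network",
]


class TUCode(IntEnum):
    """Three-state transcriptional status used in kymographs."""

    OFF = 0  # TU repressed
    ON_IDLE = 1  # active TU, no active ON TF within binding range
    ON_TRANSCRIBING = 2  # active TU bound by >= 1 active ON TF


# --------------------------------------------------------------------------
# activity and kymographs
# --------------------------------------------------------------------------

def _frame_code(state: SystemState, tu_idx: np.ndarray, r_bind: float) -> np.ndarray:
    codes = np.full(len(tu_idx), TUCode.ON_IDLE, dtype=np.int8)
    repressed = state.chromatin_state[tu_idx] == ChromatinState.TU_REPRESSED
    codes[repressed] = TUCode.OFF
    act_on = (state.tf_species == Species.ACTIVE) & (state.tf_state == TFState.ON)
    if act_on.any():
        p = state.tf_pos[act_on]
        d = min_image(state.pos[tu_idx][:, None, :] - p[None, :, :], state.box_length)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        bound = (r2 <= r_bind * r_bind).any(axis=1)
        codes[bound & ~repressed] = TUCode.ON_TRANSCRIBING
    return codes


def frame_tu_codes(state: SystemState, r_bind: float) -> np.ndarray:
    """Per-TU three-state code for a single frame (TUs in ascending bead order)."""
    return _frame_code(state, state.tu_indices, r_bind)


def tu_activity(frames, tu_id: int, r_bind: float) -> float:
    """Fraction of frames in which TU ``tu_id`` (1-based) is transcribing.

    A frame counts iff the TU is in the active state and at least one
    active ON TF lies within ``r_bind`` (closed boundary).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    idx = int(tu_id) - 1
    if idx < 0 or idx >= frames[0].n_beads or not frames[0].is_tu[idx]:
        raise ValueError(f"bead {tu_id} is not a TU")
    hits = [
        _frame_code(f, np.array([idx]), r_bind)[0] == TUCode.ON_TRANSCRIBING
        for f in frames
    ]
    return float(np.mean(hits))


def kymograph(frames, tu_ids, r_bind: float) -> pd.DataFrame:
    """TU-by-time matrix of :class:`TUCode` values.

    Rows are indexed by 1-based TU id, columns by frame time.
    """
    frames = list(frames)
    tu_ids = np.asarray(tu_ids, dtype=np.int64)
    idx = tu_ids - 1
    data = np.stack([_frame_code(f, idx, r_bind) for f in frames], axis=1)
    return pd.DataFrame(data, index=tu_ids, columns=[f.time for f in frames])


# --------------------------------------------------------------------------
# TF clusters
# --------------------------------------------------------------------------

@dataclass
class ClusterPartition:
    """Single-linkage partition of TF particles at one frame.

    ``clusters`` are disjoint, sorted tuples of TF ids covering every input
    particle (singletons allowed), ordered by smallest member, so the
    partition is independent of input order and labelling.
    """

    time: float
    clusters: list
    positions: np.ndarray
    box_length: float
    species: np.ndarray | None = None
    ids: np.ndarray | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=np.int64)

    def composition(self) -> list[dict]:
        """Per-cluster member counts by TF species."""
        if self.species is None:
            raise ValueError("partition was built without species information")
        out = []
        for c in self.clusters:
            sp = self.species[np.searchsorted(self.ids, c)]
            out.append({
                "active": int(np.sum(sp == Species.ACTIVE)),
                "repressive": int(np.sum(sp == Species.REPRESSIVE)),
            })
        return out

    def radial_profiles(self) -> list[pd.DataFrame]:
        """Per-cluster member distances from the cluster centroid.

        Positions are unwrapped relative to the first member before the
        centroid is taken (valid for clusters smaller than half the box).
        """
        out = []
        for c in self.clusters:
            rows = np.searchsorted(self.ids, c)
            p = self.positions[rows]
            rel = min_image(p - p[0], self.box_length)
            centroid = rel.mean(axis=0)
            r = np.linalg.norm(rel - centroid, axis=1)
            df = pd.DataFrame({"tf_id": list(c), "distance": r})
            if self.species is not None:
                df["species"] = [
                    Species(int(s)).name.lower() for s in self.species[rows]
                ]
            out.append(df)
        return out


def detect_clusters(
    tf_positions: np.ndarray,
    r_clust: float,
    box: float,
    species: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    time: float = 0.0,
) -> ClusterPartition:
    """Single-linkage clusters: connected components of the graph joining
    pairs with minimum-image distance <= ``r_clust``."""
    p = np.atleast_2d(np.asarray(tf_positions, dtype=float))
    n = len(p)
    ids = np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, dtype=np.int64)
    if n == 0:
        return ClusterPartition(time, [], p, box, species, ids)
    d = min_image(p[:, None, :] - p[None, :, :], box)
    adj = np.einsum("ijk,ijk->ij", d, d) <= r_clust * r_clust
    # union-find over the adjacency's upper triangle
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ii, jj = np.nonzero(np.triu(adj, k=1))
    for a, b in zip(ii, jj):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(a) for a in range(n)])
    clusters = [
        tuple(sorted(ids[roots == lab].tolist()))
        for lab in np.unique(roots)
    ]
    clusters.sort(key=lambda c: c[0])
    return ClusterPartition(time, clusters, p, box,
                            None if species is None else np.asarray(species), ids)


def mean_active_cluster_size(
    partitions,
    min_size: int = 2,
) -> np.ndarray:
    """Per-frame mean cluster size over clusters of size >= ``min_size``.

    The partitions are expected to already be restricted to the TFs of
    interest (e.g. active ON TFs).  Frames with no qualifying cluster
    report 0.
    """
    out = np.zeros(len(partitions))
    for k, part in enumerate(partitions):
        sizes = part.sizes
        sizes = sizes[sizes >= min_size]
        out[k] = sizes.mean() if len(sizes) else 0.0
    return out


def active_tf_partition(
    state: SystemState,
    r_clust: float,
    on_only: bool = True,
) -> ClusterPartition:
    """Cluster partition of the active-species TFs of one frame."""
    mask = state.tf_species == Species.ACTIVE
    if on_only:
        mask &= state.tf_state == TFState.ON
    ids = np.flatnonzero(mask)
    return detect_clusters(
        state.tf_pos[mask], r_clust, state.box_length,
        species=state.tf_species[mask], ids=ids, time=state.time,
    )


# --------------------------------------------------------------------------
# noise and correlation networks
# --------------------------------------------------------------------------

def boomerang_stats(
    activities: np.ndarray,
    tu_ids=None,
    noise_metric: str = "sd",
) -> pd.DataFrame:
    """Per-TU mean and dispersion of activity across replicas.

    ``activities`` has shape (n_tu, n_replicas).  The dispersion defaults to
    the standard deviation (sigma_a,TU); ``noise_metric="var"`` reports the
    variance instead.
    """
    a = np.asarray(activities, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("need a (n_tu, n_replicas) matrix with >= 2 replicas")
    if noise_metric not in ("sd", "var"):
        raise ValueError("noise_metric must be 'sd' or 'var'")
    mean = a.mean(axis=1)
    disp = a.std(axis=1, ddof=1)  # sample dispersion across replicas
    if noise_metric == "var":
        disp = disp ** 2
    tu_ids = np.arange(1, a.shape[0] + 1) if tu_ids is None else np.asarray(tu_ids)
    return pd.DataFrame({"tu_id": tu_ids, "mean_a_tu": mean, "sigma_a_tu": disp})


@dataclass
class CorrelationNetwork:
    """Thresholded signed Pearson correlation network over TUs."""

    tu_ids: np.ndarray
    matrix: np.ndarray  # full symmetric Pearson matrix, unit diagonal
    threshold: float
    graph: nx.Graph

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"tu_i": u, "tu_j": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["tu_i", "tu_j", "r", "sign"])


def correlation_network(
    activities: np.ndarray,
    tu_ids=None,
    threshold: float = 0.25,
) -> CorrelationNetwork:
    """Pearson correlations of per-replica TU activities, thresholded.

    An undirected edge (with its sign) joins every TU pair with |r| >
    ``threshold``.  TUs with zero variance across replicas have undefined
    correlations and contribute no edges (a warning is emitted).
    """
    a = np.asarray(activities, dtype=float)
    if a.ndim != 2 or a.shape[1] < 3:
        raise ValueError("need a (n_tu, n_replicas) matrix with >= 3 replicas")
    n_tu = a.shape[0]
    tu_ids = np.arange(1, n_tu + 1) if tu_ids is None else np.asarray(tu_ids)
    sd = a.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} TU(s) with zero variance across replicas: "
            "no edges for these TUs",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(a)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    graph = nx.Graph()
    graph.add_nodes_from(int(t) for t in tu_ids)
    for i in range(n_tu):
        for j in range(i + 1, n_tu):
            rij = r[i, j]
            if np.isfinite(rij) and abs(rij) > threshold:
                graph.add_edge(
                    int(tu_ids[i]), int(tu_ids[j]),
                    r=float(rij), sign="+" if rij > 0 else "-",
                )
    return CorrelationNetwork(tu_ids=tu_ids, matrix=r, threshold=threshold, graph=graph)
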