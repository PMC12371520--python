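"""Deterministic test fixtures (all synthetic, generated at run time).

Each fixture is an on-disk bundle exercising one part of the pipeline:

* ``smoke_tiny``: a tiny runnable configuration (end-to-end smoke run);
* ``forced_binding``: a two-particle configuration with a repressive ON TF
  pinned at binding distance from a single TU, for the silencing/recovery
  renewal-process check;
* ``cluster_toy``: hand-placed TF positions in well-separated blobs with
  the expected single-linkage partition;
* ``correlation_toy``: a replica activity matrix with a planted correlated
  and a planted anti-correlated TU pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import dump_config, preset
from .core import ChromatinState, SystemState
from .trajio import write_frames

__all__ = ["make_fixture", "FIXTURE_KINDS", "forced_binding_state"]

FIXTURE_KINDS = ("smoke_tiny", "forced_binding", "cluster_toy", "correlation_toy")


def forced_binding_state(separation: float = 1.0, box: float = 20.0) -> SystemState:
    """One TU bead plus one repressive ON TF pinned within binding range."""
    pos = np.array([[10.0, 10.0, 10.0], [10.0 + separation, 10.0, 10.0]])
    return SystemState(
        pos=pos,
        n_beads=1,
        is_tu=np.array([True]),
        chromatin_state=np.array([ChromatinState.TU_ACTIVE], dtype=np.int8),
        recovery_deadline=np.array([-1], dtype=np.int64),
        tf_species=np.array([1], dtype=np.int8),  # repressive
        tf_state=np.array([1], dtype=np.int8),  # ON
        box_length=box,
    )


def _cluster_toy(rng: np.random.Generator):
    """12 TFs in 3 tight blobs (5 + 4 + 3) far apart; r_clust = 2 sigma."""
    box = 40.0
    centres = np.array([[5.0, 5.0, 5.0], [20.0, 20.0, 20.0], [35.0, 5.0, 20.0]])
    sizes = (5, 4, 3)
    pos = []
    for c, m in zip(centres, sizes):
        # members within 0.8 sigma of the blob centre -> pair distances < 2
        pos.append(c + rng.uniform(-0.4, 0.4, size=(m, 3)))
    pos = np.vstack(pos)
    expected = [tuple(range(0, 5)), tuple(range(5, 9)), tuple(range(9, 12))]
    return pos, box, expected


def _correlation_toy(rng: np.random.Generator):
    """8 TUs x 60 replicas; TUs 1-2 planted r ~ 0.9, TUs 3-4 anti-correlated."""
    n_rep = 60
    base = rng.normal(0.5, 0.1, size=n_rep)
    a = np.empty((8, n_rep))
    a[0] = base + rng.normal(0.0, 0.035, size=n_rep)
    a[1] = base + rng.normal(0.0, 0.035, size=n_rep)
    a[2] = 0.5 + (base - 0.5) + rng.normal(0.0, 0.02, size=n_rep)
    a[3] = 0.5 - (base - 0.5) + rng.normal(0.0, 0.02, size=n_rep)
    for i in range(4, 8):
        a[i] = rng.normal(0.5, 0.1, size=n_rep)
    return np.clip(a, 0.0, 1.0)


def make_fixture(kind: str, seed: int, outdir) -> dict:
    """Generate fixture ``kind`` under ``outdir``; returns a path manifest."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict = {"kind": kind}

    if kind == "smoke_tiny":
        cfg = preset("smoke_tiny").with_updates(seed=int(seed))
        p = outdir / "config.toml"
        dump_config(cfg, p)
        paths["config"] = str(p)

    elif kind == "forced_binding":
        state = forced_binding_state()
        p = outdir / "state.xyz"
        write_frames([state], p, fmt="xyz")
        meta = {"tu_id": 1, "tf_id": 0, "separation": 1.0, "r_bind": 1.8}
        mp = outdir / "meta.json"
        mp.write_text(json.dumps(meta, indent=2))
        paths.update(state=str(p), meta=str(mp))

    elif kind == "cluster_toy":
        pos, box, expected = _cluster_toy(rng)
        df = pd.DataFrame(pos, columns=["x", "y", "z"])
        df.insert(0, "tf_id", np.arange(len(pos)))
        p = outdir / "tf_positions.tsv"
        df.to_csv(p, sep="\t", index=False)
        mp = outdir / "expected.json"
        mp.write_text(json.dumps(
            {"box_length": box, "r_clust": 2.0,
             "clusters": [list(c) for c in expected]}, indent=2))
        paths.update(positions=str(p), expected=str(mp))

    elif kind == "correlation_toy":
        a = _correlation_toy(rng)
        df = pd.DataFrame(a, index=pd.Index(range(1, 9), name="tu_id"))
        p = outdir / "activities.tsv"
        df.to_csv(p, sep="\t")
        mp = outdir / "expected.json"
        mp.write_text(json.dumps(
            {"threshold": 0.25,
             "planted_edges": [
                 {"tu_i": 1, "tu_j": 2, "sign": "+"},
                 {"tu_i": 3, "tu_j": 4, "sign": "-"},
             ]}, indent=2))
        paths.update(activities=str(p), expected=str(mp))

    return paths
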