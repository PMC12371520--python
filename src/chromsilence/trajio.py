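"""Trajectory, table and network writers/readers.

Trajectories are plain text: extended-XYZ frames (columns: particle kind,
state code, x, y, z) or LAMMPS-style dump.  Tables are TSV; correlation
networks are written both as an edge-list TSV and GraphML.  State codes map
bijectively to the seven particle kinds (NS / active TU / repressed TU and
the four TF species-state combinations).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import CODE_NAMES, NAME_CODES, SystemState

__all__ = [
    "write_frames",
    "read_frames",
    "write_events",
    "read_events",
    "write_kymograph",
    "save_kymograph_png",
    "write_network",
    "write_manifest",
]

def _frame_codes(state: SystemState) -> np.ndarray:
    return state.type_codes()


def _state_from_arrays(pos, codes, box, time, step) -> SystemState:
    codes = np.asarray(codes, dtype=np.int64)
    bead_mask = codes < 3
    n_beads = int(bead_mask.sum())
    if not bead_mask[:n_beads].all():
        raise ValueError("malformed frame: beads must precede TFs")
    chrom = codes[:n_beads].astype(np.int8)
    tf = codes[n_beads:] - 3
    return SystemState(
        pos=np.asarray(pos, dtype=float),
        n_beads=n_beads,
        is_tu=chrom > 0,
        chromatin_state=chrom,
        recovery_deadline=np.full(n_beads, -1, dtype=np.int64),
        tf_species=(tf // 2).astype(np.int8),
        tf_state=(tf % 2).astype(np.int8),
        box_length=float(box),
        step=int(step),
        time=float(time),
    )


def write_frames(frames, path, fmt: str = "xyz") -> None:
    """Write frames as extended XYZ (default) or LAMMPS-style dump."""
    frames = list(frames)
    path = Path(path)
    with open(path, "w") as fh:
        for f in frames:
            if fmt == "xyz":
                _write_xyz_frame(fh, f)
            elif fmt == "lammps":
                _write_lammps_frame(fh, f)
            else:
                raise ValueError(f"unknown trajectory format {fmt!r}")


def _write_xyz_frame(fh, state: SystemState) -> None:
    n = state.n_beads + state.n_tf
    codes = _frame_codes(state)
    L = state.box_length
    fh.write(f"{n}\n")
    fh.write(
        f'Lattice="{float(L)!r} 0.0 0.0 0.0 {float(L)!r} 0.0 0.0 0.0 {float(L)!r}" '
        f"Properties=kind:S:1:code:I:1:pos:R:3 "
        f"Time={float(state.time)!r} Step={int(state.step)}\n"
    )
    for i in range(n):
        x, y, z = (float(v) for v in state.pos[i])
        fh.write(f"{CODE_NAMES[int(codes[i])]} {int(codes[i])} {x!r} {y!r} {z!r}\n")


def _write_lammps_frame(fh, state: SystemState) -> None:
    n = state.n_beads + state.n_tf
    codes = _frame_codes(state)
    L = state.box_length
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{int(state.step)} {float(state.time)!r}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{n}\n")
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for _ in range(3):
        fh.write(f"0.0 {float(L)!r}\n")
    fh.write("ITEM: ATOMS id type x y z\n")
    for i in range(n):
        x, y, z = (float(v) for v in state.pos[i])
        fh.write(f"{i + 1} {int(codes[i])} {x!r} {y!r} {z!r}\n")


def read_frames(path, fmt: str = "xyz") -> list[SystemState]:
    """Read a trajectory written by :func:`write_frames` (lossless for
    positions, kinds and state codes)."""
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "lammps":
        return _read_lammps(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_xyz(path) -> list[SystemState]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k])
        except ValueError as exc:
            raise ValueError(f"malformed XYZ frame header at line {k + 1}") from exc
        header = lines[k + 1]
        lat = re.search(r'Lattice="([^"]+)"', header)
        if lat is None:
            raise ValueError(f"malformed XYZ frame header at line {k + 2}")
        box = float(lat.group(1).split()[0])
        tm = re.search(r"Time=(\S+)", header)
        sm = re.search(r"Step=(\d+)", header)
        time = float(tm.group(1)) if tm else 0.0
        step = int(sm.group(1)) if sm else 0
        pos = np.empty((n, 3))
        codes = np.empty(n, dtype=np.int64)
        for i in range(n):
            parts = lines[k + 2 + i].split()
            name, code = parts[0], int(parts[1])
            if NAME_CODES[name] != code:
                raise ValueError(f"inconsistent kind/code at line {k + 3 + i}")
            codes[i] = code
            pos[i] = [float(v) for v in parts[2:5]]
        frames.append(_state_from_arrays(pos, codes, box, time, step))
        k += 2 + n
    return frames


def _read_lammps(path) -> list[SystemState]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].startswith("ITEM: TIMESTEP"):
            raise ValueError(f"malformed dump frame header at line {k + 1}")
        step_parts = lines[k + 1].split()
        step = int(step_parts[0])
        time = float(step_parts[1]) if len(step_parts) > 1 else 0.0
        n = int(lines[k + 3])
        box = float(lines[k + 5].split()[1])
        pos = np.empty((n, 3))
        codes = np.empty(n, dtype=np.int64)
        for i in range(n):
            parts = lines[k + 9 + i].split()
            codes[i] = int(parts[1])
            pos[i] = [float(v) for v in parts[2:5]]
        frames.append(_state_from_arrays(pos, codes, box, time, step))
        k += 9 + n
    return frames


# --------------------------------------------------------------------------
# event logs, tables, networks
# --------------------------------------------------------------------------

def write_events(events, path) -> None:
    """Append-only TSV event log: step, time, tu_id (1-based), event."""
    df = pd.DataFrame(
        [(e.step, e.time, e.tu_id, e.kind) for e in events],
        columns=["step", "time", "tu_id", "event"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_kymograph(kymo: pd.DataFrame, path) -> None:
    """Kymograph matrix as TSV (rows: 1-based TU ids, columns: frame times)."""
    kymo.to_csv(path, sep="\t", index_label="tu_id")


def save_kymograph_png(kymo: pd.DataFrame, path) -> None:
    """Portable image of the kymograph using the three-colour coding
    (black = OFF, yellow = ON idle, red = ON transcribing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    fig, ax = plt.subplots(figsize=(8, 3))
    cmap = ListedColormap(["black", "gold", "red"])
    ax.imshow(kymo.to_numpy(), aspect="auto", interpolation="nearest",
              cmap=cmap, vmin=0, vmax=2,
              extent=(float(kymo.columns[0]), float(kymo.columns[-1]),
                      len(kymo.index) - 0.5, -0.5))
    ax.set_yticks(range(len(kymo.index)))
    ax.set_yticklabels(kymo.index)
    ax.set_xlabel("time (tau_B)")
    ax.set_ylabel("TU bead ID")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_network(net, basepath) -> None:
    """Write a correlation network as edge-list TSV and GraphML."""
    base = Path(basepath)
    net.edges.to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    nx.write_graphml(net.graph, base.with_suffix(".graphml"))


def write_manifest(path, config_dict: dict, **extra) -> None:
    """Machine-readable run manifest (resolved config + provenance)."""
    import chromsilence

    payload = {
        "package": "chromsilence",
        "version": chromsilence.__version__,
        "rng_order": extra.pop("rng_order", "rng-order-1"),
        "config": config_dict,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
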