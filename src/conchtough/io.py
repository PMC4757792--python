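"""Plain-text I/O: CSV tables, JSON-lines trajectories, legacy-VTK dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fracture import FractureTrajectory
from .lattice import LatticeGraph


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_ctod_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CTOD table writer with round-trip-exact float formatting.

    ``%.17g`` prints enough digits that read -> write reproduces the file
    bit for bit.
    """
    df.to_csv(path, index=False, float_format="%.17g")


def read_ctod_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"crack_extension_nm", "delta5_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"CTOD curve needs columns {sorted(required)}")
    return df


def write_trajectory_jsonl(traj: FractureTrajectory, path: str | Path) -> None:
    """One JSON object per bond-breaking event, plus a trailing summary line."""
    with open(path, "w") as fh:
        for e in traj.events:
            fh.write(json.dumps({
                "bond": int(e.bond),
                "displacement": e.displacement,
                "force": e.force,
                "dissipated": e.dissipated,
                "crack_advance": e.crack_advance,
            }) + "\n")
        fh.write(json.dumps({
            "summary": True,
            "work_input": traj.work_input,
            "stored_final": traj.stored_final,
            "dissipated_total": traj.dissipated_total,
            "separated": traj.separated,
        }) + "\n")


def write_lattice_vtk(lattice: LatticeGraph, path: str | Path,
                      point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK polydata dump of the lattice (alive bonds as lines)."""
    pts = lattice.coords
    alive = lattice.bonds[lattice.alive]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nconchtough lattice\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for x, y in pts:
            fh.write(f"{x:.6f} {y:.6f} 0.0\n")
        fh.write(f"LINES {len(alive)} {3 * len(alive)}\n")
        for a, b in alive:
            fh.write(f"2 {a} {b}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{v:.6e}\n")
                else:
                    fh.write(f"VECTORS {name} float\n")
                    for row in arr:
                        fh.write(f"{row[0]:.6e} {row[1]:.6e} 0.0\n")
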