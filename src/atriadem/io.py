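"""Serialisation: cell-state snapshots, time-series CSV, particle/edge
tables, legacy-VTK point snapshots and run manifests.

All formats are plain text.  Floating-point values are written with
``repr`` round-trip precision, so save -> load is bit-exact.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_dynamics import (CellParams, CellState, STATE_NAMES, monitored)

__all__ = [
    "write_cell_snapshot", "read_cell_snapshot", "write_timeseries",
    "write_particles_csv", "write_edges_csv", "write_vtk_points",
    "write_manifest",
]


def write_cell_snapshot(state: CellState, path,
                        params: CellParams | None = None) -> None:
    """Flat key,value CSV of the monitored variable set in its documented
    ordering (32 states followed by the derived quantities).  The state
    rows round-trip bit-exactly through :func:`read_cell_snapshot`."""
    mon = monitored(state, 0.0, params or CellParams())
    with open(path, "w") as fh:
        fh.write("variable,value\n")
        for name, value in mon.items():
            fh.write(f"{name},{value!r}\n")


def read_cell_snapshot(path) -> CellState:
    """Rebuild a CellState from a snapshot CSV (derived rows are ignored)."""
    table = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("variable,"):
            raise ValueError(f"{path}: not a cell snapshot file")
        for line in fh:
            name, value = line.strip().split(",", 1)
            table[name] = float(value)
    missing = [n for n in STATE_NAMES if n not in table]
    if missing:
        raise ValueError(f"{path}: missing state variables {missing}")
    return CellState(np.array([table[n] for n in STATE_NAMES]))


def write_timeseries(path, t_ms, V_mV, Cai_mM, F_active, SL_um, L_um) -> None:
    """Single-cell time-series CSV with the documented header."""
    df = pd.DataFrame({
        "time_ms": t_ms, "V_mV": V_mV, "Cai_mM": Cai_mM,
        "F_active_norm": F_active, "SL_um": SL_um, "L_um": L_um,
    })
    df.to_csv(path, index=False)


def write_particles_csv(tissue, path) -> None:
    """Particle table CSV: particle id, clump id, x/y (um), radius (um)."""
    p = tissue.particle_table()
    df = pd.DataFrame(p, columns=["particle", "clump", "x_um", "y_um", "r_um"])
    df["particle"] = df["particle"].astype(int)
    df["clump"] = df["clump"].astype(int)
    df.to_csv(path, index=False)


def write_edges_csv(tissue, path) -> None:
    """Conduction-graph edge list CSV (cell_a, cell_b, conductance_nS)."""
    df = pd.DataFrame({"cell_a": tissue.ea, "cell_b": tissue.eb})
    df["conductance_nS"] = tissue.conductance_nS
    df.to_csv(path, index=False)


def write_vtk_points(tissue, path, values: dict | None = None) -> None:
    """Legacy-VTK (ASCII) point file of particle centres, with particle
    radius and optional per-cell scalar fields for visualisation."""
    p = tissue.particle_table()
    n = len(p)
    npart = tissue.npart
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("atriadem particle snapshot\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for row in p:
            fh.write(f"{row[2]:.6f} {row[3]:.6f} 0.0\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS radius_um float 1\nLOOKUP_TABLE default\n")
        for row in p:
            fh.write(f"{row[4]:.6f}\n")
        for name, per_cell in (values or {}).items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in np.repeat(np.asarray(per_cell, float), npart):
                fh.write(f"{v:.6g}\n")


def write_manifest(path, config=None, extra: dict | None = None) -> None:
    """Reproducibility manifest: code version, platform, config echo."""
    manifest = {
        "package": "atriadem",
        "version": __version__,
        "python": platform.python_version(),
    }
    if config is not None:
        from dataclasses import asdict
        manifest["config"] = asdict(config)
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
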