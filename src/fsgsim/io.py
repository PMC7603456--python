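"""Readers and writers: WSS series CSV, legacy-ASCII VTK polydata, HDF5 checkpoints.

The CSV schema for WSS time series is long-format with columns
``time, point_id, taux, tauy, tauz, nx, ny, nz`` (SI units).  VTK output
uses the plain-text legacy polydata layout (POINTS / LINES / POINT_DATA)
so fields are viewable in any VTK-aware tool; the reader supports the same
layout.  Checkpoints store every evolving array of an
:class:`~fsgsim.pipeline.EvolutionState` so a run can be restarted
bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .flow import WssTimeSeries
from .geometry import EquilibriumField, FiberField, IdealGeometry, MaterialField
from .pipeline import EvolutionState

__all__ = ["write_wss_csv", "read_wss_csv", "write_vtk_polydata",
           "read_vtk_polydata", "save_state", "load_state"]


def write_wss_csv(path: str | Path, series: dict[int, WssTimeSeries]) -> None:
    """Write per-point WSS time series to long-format CSV."""
    frames = []
    for pid, s in series.items():
        frames.append(pd.DataFrame({
            "time": s.times, "point_id": pid,
            "taux": s.vectors[:, 0], "tauy": s.vectors[:, 1], "tauz": s.vectors[:, 2],
            "nx": s.normal[0], "ny": s.normal[1], "nz": s.normal[2]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_wss_csv(path: str | Path) -> dict[int, WssTimeSeries]:
    """Read per-point WSS time series from long-format CSV."""
    df = pd.read_csv(path)
    required = {"time", "point_id", "taux", "tauy", "tauz", "nx", "ny", "nz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"WSS CSV missing columns: {sorted(missing)}")
    out: dict[int, WssTimeSeries] = {}
    for pid, grp in df.groupby("point_id"):
        grp = grp.sort_values("time")
        out[int(pid)] = WssTimeSeries(
            times=grp["time"].to_numpy(),
            vectors=grp[["taux", "tauy", "tauz"]].to_numpy(),
            normal=grp[["nx", "ny", "nz"]].iloc[0].to_numpy())
    return out


def write_vtk_polydata(path: str | Path, points: np.ndarray,
                       point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a polyline through ``points`` with point data as legacy ASCII VTK."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    lines = ["# vtk DataFile Version 3.0", "fsgsim field", "ASCII",
             "DATASET POLYDATA", f"POINTS {n} double"]
    lines += [" ".join(f"{c:.9e}" for c in p) for p in points]
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                lines += [f"{v:.9e}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{c:.9e}" for c in v) for v in arr]
            else:
                raise ValueError(f"unsupported point-data shape {arr.shape} for {name!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read points and point data from the legacy ASCII layout written here."""
    tokens = Path(path).read_text().splitlines()
    i = 0
    points = None
    data: dict[str, np.ndarray] = {}
    n = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            points = np.array([[float(x) for x in tokens[i + 1 + j].split()]
                               for j in range(n)])
            i += n
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = [float(tokens[i + 2 + j]) for j in range(n)]
            data[name] = np.array(vals)
            i += n + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = [[float(x) for x in tokens[i + 1 + j].split()] for j in range(n)]
            data[name] = np.array(vals)
            i += n
        i += 1
    if points is None:
        raise ValueError(f"no POINTS section in {path}")
    return points, data


_GEO_KEYS = ("s", "blend_pos", "sphericity", "profile_radius", "depth")
_MAT_KEYS = ("K_e", "K_sm", "K_c", "kappa", "m_e", "m_c", "m_sm",
             "recruitment", "attachment")
_EQ_KEYS = ("lam_circ", "lam_merid", "lam_rad", "jacobian", "current_radius",
            "lam4", "residual")


def save_state(state: EvolutionState, path: str | Path,
               config_hash: str = "") -> None:
    """Checkpoint an evolution state (HDF5) for bit-identical restart."""
    with h5py.File(path, "w") as f:
        f.attrs["step"] = state.step
        f.attrs["time"] = state.time
        f.attrs["config_hash"] = config_hash
        g = f.create_group("geometry")
        for k in _GEO_KEYS:
            g[k] = getattr(state.geometry, k)
        g["region"] = np.array([r.encode() for r in state.geometry.region])
        g.attrs["parent_radius"] = state.geometry.parent_radius
        g.attrs["sac_height"] = state.geometry.sac_height
        g["thickness"] = state.geometry.thickness
        mt = f.create_group("material")
        for k in _MAT_KEYS:
            mt[k] = getattr(state.material, k)
        fb = f.create_group("fibers")
        fb["angles"] = state.fibers.angles
        fb["umbilic"] = state.fibers.umbilic
        for tag in ("eq_dias", "eq_sys"):
            eq = getattr(state, tag)
            if eq is not None:
                ge = f.create_group(tag)
                ge.attrs["pressure"] = eq.pressure
                for k in _EQ_KEYS:
                    ge[k] = getattr(eq, k)
        for k in ("wss_magnitude", "wssar_field", "stimulus"):
            v = getattr(state, k)
            if v is not None:
                f[k] = v


def load_state(path: str | Path) -> EvolutionState:
    """Load a checkpointed evolution state."""
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        geometry = IdealGeometry(
            **{k: g[k][()] for k in _GEO_KEYS},
            region=np.array([r.decode() for r in g["region"][()]]),
            parent_radius=float(g.attrs["parent_radius"]),
            sac_height=float(g.attrs["sac_height"]),
            thickness=g["thickness"][()])
        material = MaterialField(**{k: f["material"][k][()] for k in _MAT_KEYS})
        fibers = FiberField(angles=f["fibers"]["angles"][()],
                            umbilic=f["fibers"]["umbilic"][()].astype(bool))
        state = EvolutionState(step=int(f.attrs["step"]), time=float(f.attrs["time"]),
                               geometry=geometry, material=material, fibers=fibers)
        for tag in ("eq_dias", "eq_sys"):
            if tag in f:
                ge = f[tag]
                setattr(state, tag, EquilibriumField(
                    pressure=float(ge.attrs["pressure"]),
                    **{k: ge[k][()] for k in _EQ_KEYS}))
        for k in ("wss_magnitude", "wssar_field", "stimulus"):
            if k in f:
                setattr(state, k, f[k][()])
    return state
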