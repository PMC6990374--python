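"""File formats: VTK legacy structured grids, CSV tables, JSON configs and
HDF5 recording containers.

The VTK legacy ASCII writer covers the structured-points subset needed for
label fields and nodal scalar maps (readable by ParaView/VisIt); recordings
are stored as HDF5 with times, voltages, labels and a JSON-encoded config
echo.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .geometry import Label, ScarSpec, TissueGrid
from .monodomain import SimulationConfig, VmRecording

__all__ = [
    "write_vtk_scalars", "labels_to_csv", "map_to_csv",
    "recording_to_hdf5", "recording_from_hdf5",
    "config_to_json", "RunManifest",
]


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_to_json(obj, path: str | Path | None = None, **extra) -> str:
    """Serialize a config dataclass (plus extra keys) to JSON text, with
    every default printed explicitly."""
    payload = {"schema_version": 1, "package_version": __version__}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload.update(dataclasses.asdict(obj))
    elif isinstance(obj, Mapping):
        payload.update(obj)
    else:
        raise TypeError("config must be a dataclass or mapping")
    payload.update(extra)
    text = json.dumps(payload, indent=2, default=_json_default)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# VTK legacy (ASCII) structured points
# ---------------------------------------------------------------------------

def write_vtk_scalars(path: str | Path, grid: TissueGrid,
                      point_data: Mapping[str, np.ndarray] | None = None,
                      cell_data: Mapping[str, np.ndarray] | None = None,
                      title: str = "infarctsim field") -> None:
    """Write nodal and/or element scalar fields on the regular grid as a VTK
    legacy STRUCTURED_POINTS file (ASCII).

    ``point_data`` arrays have shape (ny+1, nx+1); ``cell_data`` (ny, nx).
    NaNs are preserved (ParaView renders them as blank).
    """
    nxn, nyn = grid.nx + 1, grid.ny + 1
    h = grid.h_mm
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nxn} {nyn} 1",
        "ORIGIN 0 0 0",
        f"SPACING {h} {h} 1",
    ]
    if point_data:
        lines.append(f"POINT_DATA {nxn * nyn}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.shape != (nyn, nxn):
                raise ValueError(f"point field '{name}' has shape {arr.shape},"
                                 f" expected {(nyn, nxn)}")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:.6g}" for v in row) for row in arr)
    if cell_data:
        lines.append(f"CELL_DATA {grid.nx * grid.ny}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.shape != (grid.ny, grid.nx):
                raise ValueError(f"cell field '{name}' has shape {arr.shape},"
                                 f" expected {(grid.ny, grid.nx)}")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:.6g}" for v in row) for row in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def labels_to_csv(grid: TissueGrid, path: str | Path) -> None:
    """Element labels as CSV (flat row-major element index, label name)."""
    flat = grid.labels.ravel()
    df = pd.DataFrame({"element": np.arange(flat.size),
                       "label": [Label(v).name for v in flat]})
    df.to_csv(path, index=False)


def map_to_csv(arr: np.ndarray, path: str | Path, name: str = "value") -> None:
    """Nodal map as CSV (node index, row, col, value)."""
    nyn, nxn = arr.shape
    rr, cc = np.divmod(np.arange(arr.size), nxn)
    pd.DataFrame({"node": np.arange(arr.size), "row": rr, "col": cc,
                  name: arr.ravel()}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HDF5 recording container
# ---------------------------------------------------------------------------

def recording_to_hdf5(rec: VmRecording, path: str | Path) -> None:
    """Store a recording (times, Vm, labels, coordinates, config echo)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times_ms", data=rec.times)
        f.create_dataset("vm_mV", data=rec.vm, compression="gzip",
                         compression_opts=4)
        f.create_dataset("labels", data=rec.grid.labels)
        f.create_dataset("active", data=rec.active)
        f.create_dataset("node_x_mm", data=rec.grid.node_x_mm())
        f.create_dataset("node_y_mm", data=rec.grid.node_y_mm())
        f.attrs["h_um"] = rec.grid.h_um
        if rec.grid.scar is not None:
            f.attrs["scar_json"] = json.dumps(
                dataclasses.asdict(rec.grid.scar), default=_json_default)
        if rec.config is not None:
            f.attrs["config_json"] = config_to_json(rec.config)
        f.attrs["meta_json"] = json.dumps(
            {k: v for k, v in rec.meta.items()
             if not isinstance(v, np.ndarray)}, default=_json_default)
        f.attrs["stim_events_json"] = json.dumps(rec.stim_events)


def recording_from_hdf5(path: str | Path) -> VmRecording:
    """Load a recording written by :func:`recording_to_hdf5`."""
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        ny, nx = labels.shape
        scar = None
        if "scar_json" in f.attrs:
            d = json.loads(f.attrs["scar_json"])
            center = tuple(d["center"]) if d.get("center") else None
            scar = ScarSpec(d["isthmus_width"], d["scar_half_length"],
                            d["scar_depth"], center)
        grid = TissueGrid(nx=nx, ny=ny, h_um=float(f.attrs["h_um"]),
                          labels=labels.astype(np.int8), scar=scar)
        config = None
        if "config_json" in f.attrs:
            d = json.loads(f.attrs["config_json"])
            config = SimulationConfig(**{
                k: d[k] for k in ("dt", "t_end", "sample_interval",
                                  "beta_per_um", "cm",
                                  "diffusion_calibration", "vm_abort",
                                  "record_dtype") if k in d})
        rec = VmRecording(
            times=f["times_ms"][()], vm=f["vm_mV"][()], grid=grid,
            active=f["active"][()].astype(bool),
            stim_events=[tuple(e) for e in
                         json.loads(f.attrs["stim_events_json"])],
            config=config, meta=json.loads(f.attrs["meta_json"]))
    return rec


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

class RunManifest:
    """Collects config echo, seeds and produced files for one CLI run."""

    def __init__(self, command: str, config, root_seed: int | None = None):
        self._t0 = time.time()
        self.data = {
            "command": command,
            "package_version": __version__,
            "root_seed": root_seed,
            "config": config,
            "outputs": [],
        }

    def add_output(self, path: str | Path, kind: str) -> None:
        self.data["outputs"].append({"path": str(path), "kind": kind})

    def write(self, path: str | Path, **summary) -> None:
        self.data["summary"] = summary
        self.data["wall_clock_s"] = round(time.time() - self._t0, 3)
        Path(path).write_text(
            json.dumps(self.data, indent=2, default=_json_default) + "\n")
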