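"""Plain-text readers and writers for phantoms and simulation output.

Labelled grids and temperature snapshots are written as legacy ASCII VTK
structured-points files (cell data), which ParaView and VisIt open
directly; sensor traces go to CSV with one column per tissue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import TissueLabelGrid
from .solver import TemperatureHistory

__all__ = [
    "write_labels_vtk",
    "read_labels_vtk",
    "write_field_vtk",
    "sensor_frame",
    "write_sensor_csv",
]


def _write_structured_points_header(fh, grid: TissueLabelGrid, title: str):
    nx, ny, nz = grid.shape
    h = grid.voxel_size
    ox, oy, oz = grid.origin
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write("DATASET STRUCTURED_POINTS\n")
    # point dimensions = cell dimensions + 1 (data lives on cells)
    fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
    fh.write(f"ORIGIN {ox} {oy} {oz}\n")
    fh.write(f"SPACING {h} {h} {h}\n")
    fh.write(f"CELL_DATA {nx * ny * nz}\n")


def _cell_order(arr: np.ndarray) -> np.ndarray:
    # VTK cell ordering: x fastest, z slowest
    return arr.transpose(2, 1, 0).reshape(-1)


def write_labels_vtk(grid: TissueLabelGrid, path) -> None:
    """Write the tissue label array as legacy ASCII VTK structured points."""
    with open(path, "w") as fh:
        _write_structured_points_header(fh, grid, "pulptherm tissue labels")
        fh.write("SCALARS tissue int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        np.savetxt(fh, _cell_order(grid.labels)[None], fmt="%d")
        fh.write(f"FIELD metadata 1\ncervical_z 1 1 float\n{grid.cervical_z}\n")


def read_labels_vtk(path) -> TissueLabelGrid:
    """Read a labelled grid written by :func:`write_labels_vtk`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = spacing = origin = None
    data_start = None
    n_cells = 0
    cervical_z = 0.0
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "DIMENSIONS":
            dims = tuple(int(v) - 1 for v in tok[1:4])
        elif tok[0] == "ORIGIN":
            origin = tuple(float(v) for v in tok[1:4])
        elif tok[0] == "SPACING":
            spacing = [float(v) for v in tok[1:4]]
        elif tok[0] == "CELL_DATA":
            n_cells = int(tok[1])
        elif tok[0] == "LOOKUP_TABLE":
            data_start = i + 1
        elif tok[0] == "cervical_z":
            cervical_z = float(lines[i + 1].split()[0])
    if dims is None or spacing is None or origin is None or data_start is None:
        raise InvalidParameterError(f"{path}: not a pulptherm VTK label file")
    if len(set(spacing)) != 1:
        raise InvalidParameterError(f"{path}: anisotropic spacing unsupported")
    values: list[int] = []
    for line in lines[data_start:]:
        tok = line.split()
        if tok and tok[0] in ("FIELD", "SCALARS", "METADATA"):
            break
        values.extend(int(float(v)) for v in tok)
    flat = np.asarray(values[:n_cells], dtype=np.int8)
    if flat.size != n_cells:
        raise InvalidParameterError(f"{path}: truncated cell data")
    nx, ny, nz = dims
    labels = flat.reshape(nz, ny, nx).transpose(2, 1, 0)
    return TissueLabelGrid(
        labels=labels, voxel_size=spacing[0], origin=origin,
        cervical_z=cervical_z,
    )


def write_field_vtk(
    grid: TissueLabelGrid, field_by_dof: np.ndarray,
    voxel_of_dof: np.ndarray, path, name: str = "temperature_C",
    background_value: float = np.nan,
) -> None:
    """Write one per-voxel scalar field (e.g. a temperature snapshot)."""
    full = np.full(grid.labels.size, background_value)
    full[voxel_of_dof] = field_by_dof
    with open(path, "w") as fh:
        _write_structured_points_header(fh, grid, f"pulptherm field {name}")
        fh.write(f"SCALARS {name} float 1\n")
        fh.write("LOOKUP_TABLE default\n")
        np.savetxt(fh, _cell_order(full.reshape(grid.shape))[None], fmt="%.6f")


def sensor_frame(history: TemperatureHistory, mode: str = "max") -> pd.DataFrame:
    """Sensor traces as a DataFrame: time_s plus one column per tissue."""
    if mode not in ("max", "probe"):
        raise InvalidParameterError(f"mode must be 'max' or 'probe', got {mode!r}")
    data = {"time_s": history.times}
    for tissue in ("enamel", "dentin", "pulp", "composite"):
        if tissue in history.traces:
            data[f"{tissue}_C"] = history.traces[tissue][mode]
    return pd.DataFrame(data)


def write_sensor_csv(history: TemperatureHistory, path, mode: str = "max") -> None:
    """Write sensor traces to CSV (deterministic formatting)."""
    sensor_frame(history, mode).to_csv(path, index=False, float_format="%.8f")
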