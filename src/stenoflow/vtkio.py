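"""Legacy-VTK ASCII writers for the body-fitted grid and field snapshots.

The axisymmetric (z, r) grid is written as a ``STRUCTURED_GRID`` with one
cell in the third direction, the dialect with the widest reader support.
Fields are attached as CELL_DATA: velocity as a 3-vector (axial, radial, 0),
pressure, viscosity and the porous-zone tag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import StructuredGrid

__all__ = ["write_vtk_grid", "write_vtk_snapshot"]


def _header(f, title: str, grid: StructuredGrid) -> None:
    ni, nj = grid.ni, grid.nj
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")
    f.write("DATASET STRUCTURED_GRID\n")
    f.write(f"DIMENSIONS {ni + 1} {nj + 1} 1\n")
    f.write(f"POINTS {(ni + 1) * (nj + 1)} double\n")
    # VTK structured grids store points x-fastest: x = z, y = r, z = 0
    for j in range(nj + 1):
        for i in range(ni + 1):
            f.write(f"{grid.z[i]:.9e} {grid.r[i, j]:.9e} 0.0\n")


def _cell_scalar(f, name: str, arr: np.ndarray) -> None:
    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    for j in range(arr.shape[1]):
        for i in range(arr.shape[0]):
            f.write(f"{arr[i, j]:.9e}\n")


def write_vtk_grid(path, grid: StructuredGrid) -> None:
    """Write the grid with its zone tags and cell volumes for inspection."""
    with open(path, "w") as f:
        _header(f, "stenoflow grid", grid)
        f.write(f"CELL_DATA {grid.n_cells}\n")
        _cell_scalar(f, "zone_porous", grid.porous.astype(float))
        _cell_scalar(f, "cell_volume", grid.vol)


def write_vtk_snapshot(path, grid: StructuredGrid, uz, ur, p,
                       mu=None) -> None:
    """Write one flow snapshot (cell data: velocity vector, pressure,
    viscosity, zone tag)."""
    with open(path, "w") as f:
        _header(f, "stenoflow snapshot", grid)
        f.write(f"CELL_DATA {grid.n_cells}\n")
        f.write("VECTORS velocity double\n")
        for j in range(grid.nj):
            for i in range(grid.ni):
                f.write(f"{uz[i, j]:.9e} {ur[i, j]:.9e} 0.0\n")
        _cell_scalar(f, "pressure", p)
        if mu is not None:
            _cell_scalar(f, "viscosity", mu)
        _cell_scalar(f, "zone_porous", grid.porous.astype(float))


def write_traces_csv(path, history) -> None:
    """Per-step probe traces as CSV: time, plane id/position, area-averaged
    pressure and axial velocity, centreline velocity, mass-balance error."""
    import pandas as pd

    rows = []
    for kp, zp in enumerate(history.probe_z):
        rows.append(pd.DataFrame({
            "time_s": history.times,
            "plane": kp,
            "plane_z_m": zp,
            "p_mean_Pa": history.p_mean[:, kp],
            "uz_mean_m_per_s": history.uz_mean[:, kp],
            "uz_center_m_per_s": history.uz_center[:, kp],
            "mass_balance_err": history.mass_error,
        }))
    pd.concat(rows, ignore_index=True).to_csv(Path(path), index=False)
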