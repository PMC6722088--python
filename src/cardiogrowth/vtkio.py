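"""Minimal legacy-VTK (ASCII) writer for tetrahedral meshes and fields.

Writes DATASET UNSTRUCTURED_GRID files readable by ParaView/VisIt: points,
tet connectivity, and any number of scalar/vector point- and cell-data
arrays.  ASCII keeps outputs text-only and diffable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_unstructured"]


def _write_data_section(fh, data: dict, n: int, header: str) -> None:
    fh.write(f"{header} {n}\n")
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.shape[0] != n:
            raise ValueError(f"field {name!r} has wrong length")
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")
        elif arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.9g")
        else:
            raise ValueError(f"field {name!r} must be scalar or 3-vector")


def write_vtk_unstructured(
    path,
    vertices: np.ndarray,
    cells: np.ndarray,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    title: str = "cardiogrowth",
) -> None:
    vertices = np.asarray(vertices, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(vertices)} double\n")
        np.savetxt(fh, vertices, fmt="%.9g")
        fh.write(f"CELLS {len(cells)} {5 * len(cells)}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(len(cells), 4, dtype=np.int64), cells]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), 10, dtype=np.int64), fmt="%d")
        if point_data:
            _write_data_section(fh, point_data, len(vertices), "POINT_DATA")
        if cell_data:
            _write_data_section(fh, cell_data, len(cells), "CELL_DATA")
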