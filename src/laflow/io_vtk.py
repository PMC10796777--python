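"""Minimal legacy-VTK ASCII writers for inspection output.

Structured-points files carry cell data (signed distance, velocity,
pressure); polydata files carry pathline polylines with a per-line scalar.
Writers only — nothing in the package reads these files back.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_structured_points", "write_polylines"]


def _header(f, title):
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")


def write_structured_points(path, grid, cell_scalars=None, cell_vectors=None,
                            title="laflow field"):
    """Write cell-centered fields on a uniform grid.

    cell_scalars / cell_vectors: dicts name -> array of shape grid.n
    (+ trailing 3 for vectors).
    """
    nx, ny, nz = grid.n
    cell_scalars = cell_scalars or {}
    cell_vectors = cell_vectors or {}
    with open(path, "w") as f:
        _header(f, title)
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} {grid.origin[2]:.9g}\n")
        f.write(f"SPACING {grid.h:.9g} {grid.h:.9g} {grid.h:.9g}\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in cell_scalars.items():
            a = np.asarray(arr)
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest
            np.savetxt(f, a.transpose(2, 1, 0).reshape(-1, 1), fmt="%.8g")
        for name, arr in cell_vectors.items():
            a = np.asarray(arr)
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, a.transpose(2, 1, 0, 3).reshape(-1, 3), fmt="%.8g")


def write_polylines(path, polylines, scalars=None, scalar_name="label",
                    title="laflow pathlines"):
    """Write a set of polylines (list of (n_i, 3) arrays) with one scalar
    value per line."""
    polylines = [np.asarray(p, dtype=float) for p in polylines]
    n_pts = sum(len(p) for p in polylines)
    with open(path, "w") as f:
        _header(f, title)
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {n_pts} double\n")
        for p in polylines:
            np.savetxt(f, p, fmt="%.6g")
        size = sum(len(p) + 1 for p in polylines)
        f.write(f"LINES {len(polylines)} {size}\n")
        offset = 0
        for p in polylines:
            idx = " ".join(str(offset + i) for i in range(len(p)))
            f.write(f"{len(p)} {idx}\n")
            offset += len(p)
        if scalars is not None:
            f.write(f"CELL_DATA {len(polylines)}\n")
            f.write(f"SCALARS {scalar_name} double 1\nLOOKUP_TABLE default\n")
            for s in scalars:
                f.write(f"{float(s):.8g}\n")
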