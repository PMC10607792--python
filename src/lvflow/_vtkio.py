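"""Minimal legacy-ASCII VTK writer for meshes, surfaces and field snapshots."""

from __future__ import annotations

import numpy as np

_CELL_TYPES = {"line2": 3, "tri3": 5, "quad4": 9, "tet4": 10}


def write_vtk(path, nodes, cells, cell_kind: str, point_data=None,
              cell_data=None, title="lvflow output"):
    """Write an unstructured grid in legacy ASCII VTK format.

    ``point_data``/``cell_data`` map names to scalar (N,) or vector (N, 3)
    arrays; 2D geometry/vectors are zero-padded to 3D.
    """
    nodes = np.asarray(nodes, float)
    cells = np.asarray(cells, np.int64)
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    ctype = _CELL_TYPES[cell_kind]
    npts, ncell = len(nodes), len(cells)
    k = cells.shape[1]
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {npts} double\n")
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write(f"CELLS {ncell} {ncell * (k + 1)}\n")
        np.savetxt(fh, np.column_stack([np.full(ncell, k), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {ncell}\n")
        np.savetxt(fh, np.full(ncell, ctype), fmt="%d")
        for header, data in (("POINT_DATA %d" % npts, point_data),
                             ("CELL_DATA %d" % ncell, cell_data)):
            if not data:
                continue
            fh.write(header + "\n")
            for name, arr in data.items():
                arr = np.asarray(arr, float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    if arr.shape[1] == 2:
                        arr = np.column_stack([arr, np.zeros(len(arr))])
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
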