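"""Minimal legacy-ASCII VTK writer for the hexahedral LV mesh."""

from __future__ import annotations

import numpy as np

from .geometry import LVMesh

_VTK_HEX = 12


def write_vtk(path, mesh: LVMesh, displacement: np.ndarray | None = None,
              cell_data: dict | None = None, point_data: dict | None = None):
    """Write the mesh as a legacy VTK unstructured grid.

    Layer index, helix angle and fibre vectors are always included as cell
    data; extra scalar cell/point fields may be supplied.
    """
    cells = mesh.hexes
    n_cells = cells.shape[0]
    cdata = {"layer": mesh.layer.astype(float),
             "helix_deg": mesh.helix_deg,
             "depth_fraction": mesh.depth_fraction}
    if cell_data:
        cdata.update(cell_data)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nivcsim LV mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        fh.write(f"CELLS {n_cells} {n_cells * 9}\n")
        np.savetxt(fh, np.hstack([np.full((n_cells, 1), 8, dtype=np.int64), cells]),
                   fmt="%d")
        fh.write(f"CELL_TYPES {n_cells}\n")
        np.savetxt(fh, np.full(n_cells, _VTK_HEX, dtype=np.int64), fmt="%d")
        fh.write(f"CELL_DATA {n_cells}\n")
        for name, arr in cdata.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(arr, float), fmt="%.9g")
        fh.write("VECTORS fibre double\n")
        np.savetxt(fh, mesh.fibres, fmt="%.9g")
        wrote_pd = False
        if displacement is not None:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            wrote_pd = True
            fh.write("VECTORS displacement double\n")
            np.savetxt(fh, np.asarray(displacement, float), fmt="%.9g")
        if point_data:
            if not wrote_pd:
                fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, float), fmt="%.9g")
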