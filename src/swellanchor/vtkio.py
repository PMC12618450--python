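"""Minimal legacy-ASCII VTK writer for voxel meshes and their fields."""

from __future__ import annotations

import numpy as np

from .fem import VoxelMesh, FieldState

__all__ = ["write_vtk"]

_CELL_TYPE = {4: 9, 8: 12}  # VTK_QUAD, VTK_HEXAHEDRON


def write_vtk(path, mesh: VoxelMesh, point_data: dict = None,
              cell_data: dict = None, title: str = "swellanchor fields") -> None:
    """Write an unstructured-grid legacy VTK file (ASCII).

    ``point_data`` maps names to (n_nodes,) scalars or (n_nodes, dim)
    vectors; ``cell_data`` maps names to per-element scalars.  2D meshes are
    written with z = 0.
    """
    nodes = mesh.nodes
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    cells = mesh.elements
    nen = cells.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write(f"CELLS {len(cells)} {len(cells) * (nen + 1)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(cells), nen), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), _CELL_TYPE[nen]), fmt="%d")

        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 2:
                    if arr.shape[1] == 2:
                        arr = np.column_stack([arr, np.zeros(len(arr))])
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.9g")
        if cell_data:
            fh.write(f"CELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%.9g")


def write_field_state(path, mesh: VoxelMesh, state: FieldState, extra_cell_data: dict = None) -> None:
    """Convenience dump of one FE solution (u, sigma_vm proxy, sed, eigenstrain)."""
    cell_data = {
        "sed_J_cm3": state.sed,
        "eigenstrain": state.eigenstrain,
        "region": mesh.region.astype(float),
    }
    if extra_cell_data:
        cell_data.update(extra_cell_data)
    write_vtk(path, mesh, point_data={"displacement_mm": state.displacement},
              cell_data=cell_data)
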