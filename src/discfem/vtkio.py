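"""Minimal ASCII VTU (VTK XML unstructured grid) export.

Writes hexahedral meshes with optional point data (vectors) and cell data
(scalars, vectors or tensors) for visual audit in ParaView. Only the ASCII
subset needed by this package is implemented.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .geometry import DiscMesh

__all__ = ["write_vtu", "write_fe_deck"]

_VTK_HEXAHEDRON = 12


def _format_array(name: str, arr: np.ndarray) -> str:
    arr = np.asarray(arr)
    if arr.ndim == 1:
        ncomp, flat = 1, arr
    else:
        flat = arr.reshape(arr.shape[0], -1)
        ncomp = flat.shape[1]
        flat = flat.ravel()
    if np.issubdtype(arr.dtype, np.integer):
        dtype, fmt = "Int64", "%d"
    else:
        dtype, fmt = "Float64", "%.9g"
    body = " ".join(fmt % v for v in flat)
    return (f'<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>')


def write_vtu(path, mesh: DiscMesh,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the mesh (plus fields) as an ASCII .vtu file.

    Region labels, fiber directions and local frames are exported
    automatically when present; tensor cell data (ne, 3, 3) is flattened to
    nine components.
    """
    nn, ne = mesh.n_nodes, mesh.n_elements
    cell_data = dict(cell_data or {})
    if "region_id" not in cell_data:
        labels = sorted(set(mesh.region))
        lut = {lab: i for i, lab in enumerate(labels)}
        cell_data["region_id"] = np.array([lut[r] for r in mesh.region])
    if mesh.fiber_dirs is not None:
        fd = np.nan_to_num(mesh.fiber_dirs)
        cell_data.setdefault("fiber_1", fd[:, 0])
        cell_data.setdefault("fiber_2", fd[:, 1])
    if mesh.local_frame is not None:
        cell_data.setdefault("circumferential", mesh.local_frame[:, 0])
        cell_data.setdefault("radial", mesh.local_frame[:, 1])

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">',
             "<Points>", _format_array("points", mesh.nodes), "</Points>",
             "<Cells>",
             _format_array("connectivity", mesh.hexes.ravel()),
             _format_array("offsets", 8 * np.arange(1, ne + 1)),
             _format_array("types", np.full(ne, _VTK_HEXAHEDRON)),
             "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            parts.append(_format_array(name, np.asarray(arr)))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            parts.append(_format_array(name, np.asarray(arr)))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_fe_deck(path, mesh: DiscMesh) -> None:
    """Write a classic text input deck (nodes, elements, element sets per
    region, node sets) for cross-checking the mesh in external solvers."""
    lines = ["*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    lines.append("*ELEMENT, TYPE=C3D8")
    for e, conn in enumerate(mesh.hexes, start=1):
        lines.append(f"{e}, " + ", ".join(str(c + 1) for c in conn))
    for label in sorted(set(mesh.region)):
        els = np.flatnonzero(mesh.region == label) + 1
        lines.append(f"*ELSET, ELSET={label}")
        for k in range(0, len(els), 12):
            lines.append(", ".join(map(str, els[k:k + 12])))
    for name, ids in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name}")
        ids1 = np.asarray(ids) + 1
        for k in range(0, len(ids1), 12):
            lines.append(", ".join(map(str, ids1[k:k + 12])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
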