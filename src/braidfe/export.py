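"""Mesh, field and fiber-path writers (plain-text formats).

Legacy-ASCII VTK unstructured grids (hexahedra plus optional polyline
cells) for visualization, the Abaqus ``.inp`` dialect (C3D8 elements) for
interoperability, and CSV/JSON polylines for fiber paths.  A minimal
``.inp`` reader round-trips the meshes this package writes.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .embedded import FiberPath
from .hexfem import HexMesh

__all__ = [
    "write_vtk",
    "write_abaqus_inp",
    "read_abaqus_inp",
    "write_fiber_csv",
    "write_fiber_json",
    "read_fiber_json",
]


def write_vtk(
    path,
    mesh: HexMesh,
    point_data: dict[str, np.ndarray] | None = None,
    fibers: list[FiberPath] | None = None,
) -> None:
    """Legacy-ASCII VTK unstructured grid with hexes and fiber polylines.

    ``point_data`` maps names to per-node scalars (n,) or vectors (n, 3);
    fiber polylines are appended as extra points and poly-line cells.
    """
    mesh_pts = mesh.nodes
    fibers = fibers or []
    fiber_pts = [np.asarray(f.points) for f in fibers]
    all_pts = np.vstack([mesh_pts] + fiber_pts) if fiber_pts else mesh_pts

    lines = [
        "# vtk DataFile Version 3.0",
        "braidfe export",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(all_pts)} double",
    ]
    lines += [" ".join(f"{c:.10g}" for c in p) for p in all_pts]

    n_hex = mesh.n_elements
    cells = [(12, list(el)) for el in mesh.elements]  # VTK_HEXAHEDRON
    offset = len(mesh_pts)
    for pts in fiber_pts:
        ids = list(range(offset, offset + len(pts)))
        cells.append((4, ids))  # VTK_POLY_LINE
        offset += len(pts)
    size = sum(len(ids) + 1 for _, ids in cells)
    lines.append(f"CELLS {len(cells)} {size}")
    lines += [f"{len(ids)} " + " ".join(map(str, ids)) for _, ids in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(t) for t, _ in cells]

    if point_data:
        lines.append(f"POINT_DATA {len(all_pts)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            pad = len(all_pts) - len(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                full = np.vstack([arr, np.zeros((pad, 3))]) if pad else arr
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{c:.10g}" for c in row) for row in full]
            else:
                full = np.concatenate([arr, np.zeros(pad)]) if pad else arr
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in full]

    Path(path).write_text("\n".join(lines) + "\n")


def write_abaqus_inp(path, mesh: HexMesh, part_name: str = "PART-1") -> None:
    """Abaqus input deck with 1-based C3D8 elements."""
    lines = [f"*HEADING", f"** braidfe mesh export", f"*NODE"]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {p[0]:.10g}, {p[1]:.10g}, {p[2]:.10g}")
    lines.append(f"*ELEMENT, TYPE=C3D8, ELSET={part_name}")
    for e, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(c + 1) for c in conn))
    Path(path).write_text("\n".join(lines) + "\n")


def read_abaqus_inp(path) -> HexMesh:
    """Read the C3D8 meshes written by :func:`write_abaqus_inp`."""
    nodes: list[list[float]] = []
    elements: list[list[int]] = []
    mode = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            key = line.split(",")[0].upper()
            mode = {"*NODE": "node", "*ELEMENT": "elem"}.get(key)
            if key == "*ELEMENT" and "C3D8" not in line.upper():
                raise ValueError(f"unsupported element type in {line!r}")
            continue
        parts = [p.strip() for p in line.split(",")]
        if mode == "node":
            nodes.append([float(x) for x in parts[1:4]])
        elif mode == "elem":
            elements.append([int(x) - 1 for x in parts[1:9]])
    return HexMesh(np.asarray(nodes), np.asarray(elements, dtype=np.int64))


def write_fiber_csv(path, fibers: list[FiberPath]) -> None:
    """One row per polyline vertex: id, x, y, z, area, modulus, tag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fiber_id", "x_mm", "y_mm", "z_mm", "area_mm2", "Ef_MPa", "tag"])
        for i, f in enumerate(fibers):
            for p in f.points:
                w.writerow([i, f"{p[0]:.10g}", f"{p[1]:.10g}", f"{p[2]:.10g}",
                            f"{f.area:.10g}", f"{f.Ef:.10g}", f.tag])


def write_fiber_json(path, fibers: list[FiberPath]) -> None:
    data = [
        {
            "tag": f.tag,
            "area_mm2": f.area,
            "Ef_MPa": f.Ef,
            "points": np.asarray(f.points).tolist(),
        }
        for f in fibers
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def read_fiber_json(path) -> list[FiberPath]:
    data = json.loads(Path(path).read_text())
    return [
        FiberPath(points=np.asarray(d["points"]), area=d["area_mm2"],
                  Ef=d["Ef_MPa"], tag=d.get("tag", "fiber"))
        for d in data
    ]
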