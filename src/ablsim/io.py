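"""Mesh and field writers: VTU (ASCII XML) and Gmsh MSH v4.1.

Both formats are emitted as plain text.  Cell-data arrays written by
default: "region", "fiber", "sheet", "normal"; additional scalar cell or
point arrays (e.g. "scar" masks, activation times) can be supplied.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import LabeledMesh


def _fmt(a: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(a).ravel()
    lines = []
    for i in range(0, len(flat), per_line):
        lines.append(" ".join(f"{x:.10g}" for x in flat[i:i + per_line]))
    return "\n".join(lines)


def write_vtu(mesh: LabeledMesh, path: str | Path,
              cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write the mesh as a VTK unstructured grid (ASCII .vtu)."""
    path = Path(path)
    n_v, n_e = mesh.n_vertices, mesh.n_elements
    cd = {"region": mesh.region,
          "fiber": mesh.frames[:, :, 0],
          "sheet": mesh.frames[:, :, 1],
          "normal": mesh.frames[:, :, 2]}
    cd.update(cell_data or {})
    pd = dict(point_data or {})

    def data_array(name, arr):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        dtype = ("Int64" if np.issubdtype(arr.dtype, np.integer)
                 or arr.dtype == bool else "Float64")
        if arr.dtype == bool:
            arr = arr.astype(np.int64)
        return (f'<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                f"{_fmt(arr)}\n</DataArray>")

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_v}" NumberOfCells="{n_e}">',
        "<Points>",
        data_array("Points", mesh.vertices),
        "</Points>",
        "<Cells>",
        data_array("connectivity", mesh.tets.astype(np.int64)),
        data_array("offsets", (np.arange(1, n_e + 1) * 4).astype(np.int64)),
        data_array("types", np.full(n_e, 10, dtype=np.int64)),  # VTK_TETRA
        "</Cells>",
        "<CellData>",
        *[data_array(k, v) for k, v in cd.items()],
        "</CellData>",
        "<PointData>",
        *[data_array(k, v) for k, v in pd.items()],
        "</PointData>",
        "</Piece>",
        "</UnstructuredGrid>",
        "</VTKFile>",
    ]
    path.write_text("\n".join(parts))
    return path


def write_msh(mesh: LabeledMesh, path: str | Path) -> Path:
    """Write the mesh in Gmsh MSH 4.1 ASCII format (one volume entity)."""
    path = Path(path)
    n_v, n_e = mesh.n_vertices, mesh.n_elements
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines += ["$Entities", "0 0 0 1", "1 0 0 0 0 0 0 0 0", "$EndEntities"]
    lines += ["$Nodes", f"1 {n_v} 1 {n_v}", f"3 1 0 {n_v}"]
    lines += [str(i + 1) for i in range(n_v)]
    lines += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in mesh.vertices]
    lines += ["$EndNodes"]
    lines += ["$Elements", f"1 {n_e} 1 {n_e}", f"3 1 4 {n_e}"]  # type 4 = tet
    for i, t in enumerate(mesh.tets):
        lines.append(f"{i + 1} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}")
    lines += ["$EndElements"]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_msh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read nodes and tetrahedra back from an MSH 4.1 ASCII file."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    verts, tets = [], []
    for line in it:
        if line.strip() == "$Nodes":
            header = next(it).split()
            n_total = int(header[1])
            block = next(it).split()
            n_block = int(block[3])
            for _ in range(n_block):
                next(it)  # node tags
            for _ in range(n_block):
                verts.append([float(x) for x in next(it).split()])
            assert len(verts) == n_total
        elif line.strip() == "$Elements":
            header = next(it).split()
            block = next(it).split()
            n_block = int(block[3])
            for _ in range(n_block):
                parts = [int(x) for x in next(it).split()]
                tets.append([p - 1 for p in parts[1:5]])
    return np.asarray(verts), np.asarray(tets)


def write_activation_csv(path: str | Path, mesh: LabeledMesh,
                         activation: np.ndarray, inactive: np.ndarray,
                         summary: dict | None = None) -> Path:
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame({
        "x": mesh.vertices[:, 0], "y": mesh.vertices[:, 1],
        "z": mesh.vertices[:, 2], "t_A_ms": activation,
        "inactive": inactive.astype(int),
    })
    with open(path, "w") as fh:
        if summary:
            for k, v in summary.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return path
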