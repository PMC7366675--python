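"""Mesh and field import/export: ASCII VTK XML (.vtu) and Gmsh 2.2 (.msh).

Minimal, dependency-free readers/writers for the two interchange formats the
pipeline emits: tissue labels travel as the integer cell field ``tissue``
(physical tags in Gmsh), conductivities as the cell field ``sigma_S_per_m``;
nodal solution arrays (potentials, fields, envelope amplitudes) are written
as VTU point data.  Only tetrahedral cells are supported.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .errors import ValidationError
from .mesh import HeadMesh

__all__ = ["write_vtu", "read_vtu", "write_msh", "read_msh"]

_VTK_TETRA = 10


def _data_array(name, arr, indent="        "):
    arr = np.asarray(arr)
    if arr.dtype.kind in "iu":
        dtype, fmt = "Int64", "%d"
    else:
        dtype, fmt = "Float64", "%.17g"
    ncomp = arr.shape[1] if arr.ndim == 2 else 1
    body = "\n".join(
        indent + " ".join(fmt % x for x in np.atleast_1d(row)) for row in arr
    )
    head = (
        f'{indent[:-2]}<DataArray type="{dtype}" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n'
    )
    return head + body + f"\n{indent[:-2]}</DataArray>\n"


def write_vtu(mesh: HeadMesh, path, point_data: dict = None) -> None:
    """Write the mesh (and optional per-node arrays) as an ASCII .vtu file."""
    point_data = point_data or {}
    n, m = mesh.n_nodes, mesh.n_elements
    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "  <UnstructuredGrid>\n"
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
    ]
    parts.append("      <Points>\n")
    parts.append(_data_array("Points", mesh.nodes))
    parts.append("      </Points>\n      <Cells>\n")
    parts.append(_data_array("connectivity", mesh.tets.astype(np.int64).ravel()))
    parts.append(_data_array("offsets", 4 * np.arange(1, m + 1, dtype=np.int64)))
    parts.append(_data_array("types", np.full(m, _VTK_TETRA, dtype=np.int64)))
    parts.append("      </Cells>\n      <CellData>\n")
    parts.append(_data_array("tissue", mesh.tissue.astype(np.int64)))
    parts.append(_data_array("sigma_S_per_m", mesh.sigma))
    parts.append("      </CellData>\n")
    if point_data:
        parts.append("      <PointData>\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != n:
                raise ValidationError(f"point data {name!r} length {arr.shape[0]} != {n} nodes")
            parts.append(_data_array(name, arr))
        parts.append("      </PointData>\n")
    parts.append("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as f:
        f.write("".join(parts))


def _parse_array(elem):
    text = (elem.text or "").split()
    ncomp = int(elem.get("NumberOfComponents", "1"))
    kind = float if elem.get("type", "").startswith("Float") else int
    flat = np.array([kind(x) for x in text])
    return flat.reshape(-1, ncomp) if ncomp > 1 else flat


def read_vtu(path, tissue_names=None):
    """Read a .vtu written by :func:`write_vtu`.

    Returns ``(HeadMesh, point_data_dict)``.
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    arrays = {}
    for section in ("Points", "Cells", "CellData", "PointData"):
        sec = piece.find(section)
        if sec is None:
            continue
        for da in sec.findall("DataArray"):
            arrays[(section, da.get("Name"))] = _parse_array(da)
    types = arrays[("Cells", "types")].astype(int)
    if not np.all(types == _VTK_TETRA):
        raise ValidationError("only tetrahedral .vtu files are supported")
    conn = arrays[("Cells", "connectivity")].astype(np.int32).reshape(-1, 4)
    tissue = arrays.get(("CellData", "tissue"))
    sigma = arrays.get(("CellData", "sigma_S_per_m"))
    n_cells = conn.shape[0]
    tissue = tissue.astype(np.int16) if tissue is not None else np.zeros(n_cells, np.int16)
    sigma = sigma.astype(float) if sigma is not None else np.ones(n_cells)
    names = tissue_names or [f"tissue_{k}" for k in range(int(tissue.max()) + 1)]
    mesh = HeadMesh(
        nodes=arrays[("Points", "Points")].astype(float),
        tets=conn,
        tissue=tissue,
        sigma=sigma,
        tissue_names=list(names),
    )
    point_data = {k[1]: v for k, v in arrays.items() if k[0] == "PointData"}
    return mesh, point_data


def write_msh(mesh: HeadMesh, path) -> None:
    """Write the mesh in Gmsh 2.2 ASCII; tissue code + 1 is the physical tag."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        f.write(f"$EndNodes\n$Elements\n{mesh.n_elements}\n")
        for e, (t, code) in enumerate(zip(mesh.tets, mesh.tissue), start=1):
            tag = int(code) + 1
            f.write(f"{e} 4 2 {tag} {tag} {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}\n")
        f.write("$EndElements\n")


def read_msh(path, tissue_names=None, conductivities=None):
    """Read a Gmsh 2.2 ASCII tetrahedral mesh.

    ``conductivities`` maps tissue code (physical tag - 1) to S/m; defaults
    to 1.0 per tissue.
    """
    with open(path) as f:
        lines = f.read().splitlines()
    it = iter(lines)
    nodes, elems, tags = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            m = int(next(it))
            for _ in range(m):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                if etype != 4:
                    continue  # skip non-tetrahedral elements
                tags.append(int(parts[3]) - 1 if ntags else 0)
                elems.append([int(v) - 1 for v in parts[3 + ntags :]])
    if not elems:
        raise ValidationError(f"no tetrahedral elements found in {path}")
    tissue = np.asarray(tags, dtype=np.int16)
    conductivities = conductivities or {}
    sigma = np.array([float(conductivities.get(int(t), 1.0)) for t in tissue])
    names = tissue_names or [f"tissue_{k}" for k in range(int(tissue.max()) + 1)]
    return HeadMesh(
        nodes=np.asarray(nodes, dtype=float),
        tets=np.asarray(elems, dtype=np.int32),
        tissue=tissue,
        sigma=sigma,
        tissue_names=list(names),
    )
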