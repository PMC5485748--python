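"""Serialization: VTU and Gmsh MSH meshes/fields, CSV tables with provenance.

Plain-ASCII writers are implemented here (VTU unstructured grids with named
point/cell data arrays; Gmsh MSH v4.1 with physical groups for regions and
electrode surfaces, plus a matching reader for externally meshed geometry).
CSV tables carry ``# key=value`` provenance header lines (tool version,
seed, configuration hash) that the readers skip transparently.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import MealfError
from .geometry import Mesh

__all__ = [
    "write_vtu",
    "write_msh",
    "read_msh",
    "write_table",
    "read_table",
    "config_hash",
]


def config_hash(payload: str | bytes) -> str:
    if isinstance(payload, str):
        payload = payload.encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# VTU (XML unstructured grid, ASCII)
# ---------------------------------------------------------------------------

def _ascii(arr: np.ndarray) -> str:
    return " ".join(f"{v:.9g}" for v in np.asarray(arr, dtype=float).ravel())


def write_vtu(path: str | Path, mesh: Mesh,
              point_data: Mapping[str, np.ndarray] | None = None,
              cell_data: Mapping[str, np.ndarray] | None = None) -> Path:
    """Write the tetrahedral mesh and named data arrays as ASCII VTU.

    Complex arrays are split into ``<name>_re`` / ``<name>_im`` components.
    """
    path = Path(path)

    def split_complex(data: Mapping[str, np.ndarray] | None) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            if np.iscomplexobj(arr):
                out[f"{name}_re"] = arr.real
                out[f"{name}_im"] = arr.imag
            else:
                out[name] = arr
        return out

    pdata, cdata = split_complex(point_data), split_complex(cell_data)
    n, m = mesh.n_nodes, mesh.n_elements

    def data_xml(data: dict[str, np.ndarray], nrows: int, kind: str) -> list[str]:
        lines = [f"      <{kind}>"]
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if arr.shape[0] != nrows:
                raise MealfError(f"{kind} array {name!r} has {arr.shape[0]} rows, "
                                 f"expected {nrows}")
            lines.append(
                f'        <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">')
            lines.append("          " + _ascii(arr))
            lines.append("        </DataArray>")
        lines.append(f"      </{kind}>")
        return lines

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "          " + _ascii(mesh.nodes),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + " ".join(map(str, mesh.tets.ravel())),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + " ".join(str(4 * (i + 1)) for i in range(m)),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + " ".join(["10"] * m),  # VTK_TETRA
        "        </DataArray>",
        "      </Cells>",
    ]
    lines += data_xml(pdata, n, "PointData")
    cdata = {"region": mesh.region.astype(float), **cdata}
    lines += data_xml(cdata, m, "CellData")
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# Gmsh MSH v4.1 (ASCII)
# ---------------------------------------------------------------------------

_REGION_TAGS = {"medium": 1, "cytoplasm": 2}
_SURFACE_TAG_BASE = 100  # electrode surfaces get 101, 102, ... ; membrane 199


def write_msh(path: str | Path, mesh: Mesh) -> Path:
    """Write the labeled mesh as Gmsh MSH v4.1 ASCII.

    Physical volumes: ``medium`` (1) and ``cytoplasm`` (2).  Physical
    surfaces: one per electrode (``electrode_<id>``), the membrane
    (medium-side triangles), and the outer ground patch if present.
    """
    path = Path(path)
    surf_names: list[tuple[int, str]] = []
    surf_tris: list[tuple[int, np.ndarray]] = []
    tag = _SURFACE_TAG_BASE
    for eid, faces in mesh.electrode_faces.items():
        tag += 1
        surf_names.append((tag, f"electrode_{eid}"))
        surf_tris.append((tag, faces))
    if mesh.membrane_faces_med.shape[0] > 0:
        surf_names.append((199, "membrane"))
        surf_tris.append((199, mesh.membrane_faces_med))
    if mesh.outer_ground_faces is not None:
        surf_names.append((198, "outer_ground"))
        surf_tris.append((198, mesh.outer_ground_faces))

    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$PhysicalNames",
           str(2 + len(surf_names))]
    out.append(f'3 {_REGION_TAGS["medium"]} "medium"')
    out.append(f'3 {_REGION_TAGS["cytoplasm"]} "cytoplasm"')
    for tag, name in surf_names:
        out.append(f'2 {tag} "{name}"')
    out.append("$EndPhysicalNames")

    # entities: one discrete surface per physical surface, one volume per region
    out += ["$Entities", f"0 0 {len(surf_names)} 2"]
    for tag, _ in surf_names:
        out.append(f"{tag} 0 0 0 0 0 0 1 {tag} 0")
    for rtag in _REGION_TAGS.values():
        out.append(f"{rtag} 0 0 0 0 0 0 1 {rtag} 0")
    out.append("$EndEntities")

    n = mesh.n_nodes
    out += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    out += [str(i + 1) for i in range(n)]
    out += [f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in mesh.nodes]
    out.append("$EndNodes")

    blocks: list[tuple[int, int, int, np.ndarray]] = []  # dim, etag, etype, conn
    for tag, tris in surf_tris:
        blocks.append((2, tag, 2, np.asarray(tris)))
    for rname, rtag in _REGION_TAGS.items():
        sel = mesh.tets[mesh.region == (0 if rname == "medium" else 1)]
        if sel.shape[0]:
            blocks.append((3, rtag, 4, sel))
    total = sum(b[3].shape[0] for b in blocks)
    out += ["$Elements", f"{len(blocks)} {total} 1 {total}"]
    eid = 1
    for dim, etag, etype, conn in blocks:
        out.append(f"{dim} {etag} {etype} {conn.shape[0]}")
        for row in conn:
            out.append(f"{eid} " + " ".join(str(v + 1) for v in row))
            eid += 1
    out.append("$EndElements")
    out.append("")
    path.write_text("\n".join(out))
    return path


def read_msh(path: str | Path) -> Mesh:
    """Read a (mealf-style) Gmsh MSH v4.1 ASCII mesh.

    Recognizes physical names ``medium``/``cytoplasm`` for volumes and
    ``electrode_*``/``membrane``/``outer_ground`` surfaces.  Membrane node
    duplication is not reconstructed: externally supplied meshes are read
    as plain labeled geometry (cell-free solves and lead fields).
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag: str):
        for line in it:
            if line.strip() == tag:
                return
        raise MealfError(f"malformed MSH file: missing {tag}")

    until("$PhysicalNames")
    n_names = int(next(it))
    names: dict[int, str] = {}
    for _ in range(n_names):
        dim, tag, name = next(it).split(maxsplit=2)
        names[int(tag)] = name.strip('"')
    until("$Nodes")
    header = next(it).split()
    n_nodes = int(header[1])
    n_blocks = int(header[0])
    ids: list[int] = []
    coords: list[list[float]] = []
    for _ in range(n_blocks):
        bn = int(next(it).split()[3])
        ids += [int(next(it)) for _ in range(bn)]
        coords += [[float(v) for v in next(it).split()[:3]] for _ in range(bn)]
    nodes = np.zeros((n_nodes, 3))
    remap = {nid: i for i, nid in enumerate(ids)}
    for nid, xyz in zip(ids, coords):
        nodes[remap[nid]] = xyz

    until("$Elements")
    header = next(it).split()
    tets, region = [], []
    electrode_faces: dict[str, list] = {}
    membrane: list = []
    outer: list = []
    for _ in range(int(header[0])):
        dim, etag, etype, count = (int(v) for v in next(it).split())
        pname = names.get(etag, "")
        for _ in range(count):
            conn = [remap[int(v)] for v in next(it).split()[1:]]
            if etype == 4:
                tets.append(conn)
                region.append(1 if pname == "cytoplasm" else 0)
            elif etype == 2:
                if pname.startswith("electrode_"):
                    electrode_faces.setdefault(pname[len("electrode_"):], []).append(conn)
                elif pname == "membrane":
                    membrane.append(conn)
                elif pname == "outer_ground":
                    outer.append(conn)
    if not tets:
        raise MealfError("MSH file contains no tetrahedra")
    return Mesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int32),
        region=np.asarray(region, dtype=np.uint8),
        electrode_faces={k: np.asarray(v, dtype=np.int32)
                         for k, v in electrode_faces.items()},
        outer_ground_faces=np.asarray(outer, dtype=np.int32) if outer else None,
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# CSV tables with provenance headers
# ---------------------------------------------------------------------------

def write_table(path: str | Path, frame: pd.DataFrame,
                provenance: Mapping[str, object] | None = None) -> Path:
    path = Path(path)
    from . import __version__
    header = {"tool": f"mealf {__version__}"}
    header.update(provenance or {})
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        frame.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh)
    return frame, meta
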