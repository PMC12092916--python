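"""Mesh and tree I/O.

Meshes travel as ASCII VTU (XML unstructured grid) holding the tetrahedra
plus the tagged boundary triangles as a second cell block, so labels and
surface tags round-trip exactly, or as the CARP-style plain-text triplet
(.pts vertices, .elem tetrahedra with region tag, .lon fiber vectors, plus a
.surf file with tagged boundary triangles). The readers validate cell types
and required fields and report precisely which component is missing.
External units are coerced to mm via the ``units`` argument.

The writer/reader pair covers exactly what this package emits; it is not a
general VTK implementation.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from . import geometry as G
from . import purkinje as P
from .errors import FormatError

_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3}

VTK_TETRA, VTK_TRIANGLE = 10, 5


def _fmt_array(a) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return " ".join(repr(float(x)) for x in a.ravel())
    return " ".join(str(int(x)) for x in a.ravel())


def _data_array(parent, name, a, ncomp=1):
    a = np.asarray(a)
    el = ET.SubElement(parent, "DataArray", {
        "type": "Float64" if a.dtype.kind == "f" else "Int64",
        "Name": name, "NumberOfComponents": str(ncomp), "format": "ascii"})
    el.text = _fmt_array(a)
    return el


def write_vtu(mesh: G.LabeledMesh, path, fibers: G.FiberField | None = None,
              point_data: dict | None = None) -> None:
    """Write mesh (tets + tagged boundary triangles) as ASCII VTU."""
    nt, nf = mesh.n_elements, len(mesh.boundary_faces)
    conn = np.concatenate([mesh.tetrahedra.ravel(),
                           mesh.boundary_faces.ravel()])
    offs = np.concatenate([4 * (np.arange(nt) + 1),
                           4 * nt + 3 * (np.arange(nf) + 1)])
    types = np.concatenate([np.full(nt, VTK_TETRA), np.full(nf, VTK_TRIANGLE)])

    root = ET.Element("VTKFile", {"type": "UnstructuredGrid",
                                  "version": "0.1",
                                  "byte_order": "LittleEndian"})
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece",
                          {"NumberOfPoints": str(mesh.n_vertices),
                           "NumberOfCells": str(nt + nf)})
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", mesh.vertices, 3)
    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", conn)
    _data_array(cells, "offsets", offs)
    _data_array(cells, "types", types)

    pd = ET.SubElement(piece, "PointData")
    _data_array(pd, "apicobasal", mesh.apicobasal)
    _data_array(pd, "transmural", mesh.transmural)
    for name, arr in (point_data or {}).items():
        _data_array(pd, name, np.asarray(arr, float))

    cd = ET.SubElement(piece, "CellData")
    _data_array(cd, "region",
                np.concatenate([mesh.element_region.astype(np.int64),
                                np.full(nf, -1, np.int64)]))
    _data_array(cd, "surface_tag",
                np.concatenate([np.full(nt, -1, np.int64),
                                mesh.face_tags.astype(np.int64)]))
    if fibers is not None:
        fib = np.concatenate([fibers.vectors, np.zeros((nf, 3))])
        _data_array(cd, "fiber", fib, 3)

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _read_named_arrays(piece, section):
    sec = piece.find(section)
    out = {}
    if sec is None:
        return out
    for da in sec.findall("DataArray"):
        if da.get("format") != "ascii":
            raise FormatError("only ascii-format VTU DataArrays are supported")
        dtype = float if da.get("type", "").startswith("Float") else np.int64
        arr = np.array((da.text or "").split(), dtype=float)
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            arr = arr.reshape(-1, ncomp)
        out[da.get("Name")] = arr if dtype is float else arr.astype(np.int64)
    return out


def read_vtu(path, units: str = "mm"):
    """Read a VTU written by :func:`write_vtu`; returns (mesh, fibers).

    Raises :class:`FormatError` for non-tetrahedral volume cells or missing
    labels/fibers/coordinates.
    """
    try:
        scale = _UNIT_SCALE[units]
    except KeyError:
        raise FormatError(f"unknown unit {units!r}") from None
    root = ET.parse(path).getroot()
    piece = root.find("UnstructuredGrid/Piece")
    if piece is None:
        raise FormatError("no UnstructuredGrid Piece in file")
    pts_el = piece.find("Points/DataArray")
    verts = np.array((pts_el.text or "").split(), dtype=float).reshape(-1, 3) * scale

    cells = _read_named_arrays(piece, "Cells")
    conn, offs, types = cells["connectivity"], cells["offsets"], cells["types"]
    bad = set(np.unique(types)) - {VTK_TETRA, VTK_TRIANGLE}
    if bad:
        names = {12: "hexahedron", 13: "wedge", 14: "pyramid"}
        what = ", ".join(names.get(t, f"type {t}") for t in sorted(bad))
        raise FormatError(f"unsupported cell types ({what}); the volume mesh "
                          "must be tetrahedral")
    starts = np.concatenate(([0], offs[:-1]))
    is_tet = types == VTK_TETRA
    tets = np.stack([conn[starts[is_tet] + k] for k in range(4)], axis=1)
    is_tri = types == VTK_TRIANGLE
    tris = (np.stack([conn[starts[is_tri] + k] for k in range(3)], axis=1)
            if is_tri.any() else np.empty((0, 3), np.int64))

    cd = _read_named_arrays(piece, "CellData")
    pdata = _read_named_arrays(piece, "PointData")
    if "region" not in cd:
        raise FormatError("missing cell data 'region' (element labels)")
    if "fiber" not in cd:
        raise FormatError("missing cell data 'fiber' (per-element fiber "
                          "vectors); supply them or request the rule-based "
                          "fallback explicitly")
    for need in ("apicobasal", "transmural"):
        if need not in pdata:
            raise FormatError(f"missing point data {need!r} (normalized "
                              "coordinates)")
    if len(tris) == 0 or "surface_tag" not in cd:
        raise FormatError("missing tagged boundary triangles (surface tags)")

    region = cd["region"][is_tet].astype(np.int32)
    tags = cd["surface_tag"][is_tri].astype(np.int32)
    fib = cd["fiber"][is_tet].astype(float)

    v0 = verts[tets[:, 0]]
    d1, d2, d3 = (verts[tets[:, i]] - v0 for i in (1, 2, 3))
    vol6 = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    neg = vol6 < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()

    # recover face owners by matching sorted triples
    fkeys = {}
    for e, tet in enumerate(tets):
        for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            fkeys[tuple(sorted(tet[list(idx)]))] = e
    owners = np.array([fkeys.get(tuple(sorted(t)), -1) for t in tris],
                      np.int32)

    mesh = G.LabeledMesh(
        vertices=verts, tetrahedra=tets.astype(np.int32),
        element_region=region, boundary_faces=tris.astype(np.int32),
        face_tags=tags, face_owner=owners,
        apicobasal=pdata["apicobasal"].astype(float),
        transmural=pdata["transmural"].astype(float),
        element_volume=np.abs(vol6) / 6.0, meta={"kind": "external"})
    return mesh, G.FiberField(fib)


def load_external_mesh(path, units: str = "mm"):
    """Load an externally supplied labelled mesh; returns (mesh, fibers).

    ``path`` is a ``.vtu`` file or a CARP basename (``base.pts`` /
    ``base.elem`` / ``base.lon`` / ``base.surf``).
    """
    p = Path(path)
    if p.suffix == ".vtu":
        if not p.exists():
            raise FormatError(f"mesh file {p} does not exist")
        return read_vtu(p, units)
    return read_carp(p, units)


def write_carp(mesh: G.LabeledMesh, fibers: G.FiberField, basename) -> None:
    """Write the CARP-style plain-text triplet plus a .surf face file."""
    base = Path(basename)
    with open(base.with_suffix(".pts"), "w") as f:
        f.write(f"{mesh.n_vertices}\n")
        for x, y, z in mesh.vertices:
            f.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
    with open(base.with_suffix(".elem"), "w") as f:
        f.write(f"{mesh.n_elements}\n")
        for tet, r in zip(mesh.tetrahedra, mesh.element_region):
            f.write(f"Tt {tet[0]} {tet[1]} {tet[2]} {tet[3]} {r}\n")
    with open(base.with_suffix(".lon"), "w") as f:
        f.write("1\n")
        for v in fibers.vectors:
            f.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    with open(base.with_suffix(".surf"), "w") as f:
        f.write(f"{len(mesh.boundary_faces)}\n")
        for tri, tag in zip(mesh.boundary_faces, mesh.face_tags):
            f.write(f"Tr {tri[0]} {tri[1]} {tri[2]} {tag}\n")
    with open(base.with_suffix(".uvc"), "w") as f:
        f.write(f"{mesh.n_vertices}\n")
        for a, t in zip(mesh.apicobasal, mesh.transmural):
            f.write(f"{float(a)!r} {float(t)!r}\n")


def read_carp(basename, units: str = "mm"):
    base = Path(basename)
    scale = _UNIT_SCALE.get(units)
    if scale is None:
        raise FormatError(f"unknown unit {units!r}")
    for suffix, what in ((".pts", "vertices"), (".elem", "elements"),
                         (".lon", "fiber vectors"), (".surf", "surface tags"),
                         (".uvc", "normalized coordinates")):
        if not base.with_suffix(suffix).exists():
            raise FormatError(f"missing {base.with_suffix(suffix).name} "
                              f"({what})")
    pts = np.loadtxt(base.with_suffix(".pts"), skiprows=1) * scale
    elem_lines = Path(base.with_suffix(".elem")).read_text().splitlines()[1:]
    tets, region = [], []
    for line in elem_lines:
        parts = line.split()
        if not parts:
            continue
        if parts[0] != "Tt":
            raise FormatError(f"non-tetrahedral element record {parts[0]!r}")
        tets.append([int(x) for x in parts[1:5]])
        region.append(int(parts[5]))
    tets = np.asarray(tets, np.int32)
    lon = np.loadtxt(base.with_suffix(".lon"), skiprows=1)
    surf_lines = Path(base.with_suffix(".surf")).read_text().splitlines()[1:]
    tris, tags = [], []
    for line in surf_lines:
        parts = line.split()
        if parts:
            tris.append([int(x) for x in parts[1:4]])
            tags.append(int(parts[4]))
    uvc = np.loadtxt(base.with_suffix(".uvc"), skiprows=1)

    v0 = pts[tets[:, 0]]
    d1, d2, d3 = (pts[tets[:, i]] - v0 for i in (1, 2, 3))
    vol6 = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    neg = vol6 < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()

    mesh = G.LabeledMesh(
        vertices=pts, tetrahedra=tets,
        element_region=np.asarray(region, np.int32),
        boundary_faces=np.asarray(tris, np.int32),
        face_tags=np.asarray(tags, np.int32),
        face_owner=np.full(len(tris), -1, np.int32),
        apicobasal=uvc[:, 0], transmural=uvc[:, 1],
        element_volume=np.abs(vol6) / 6.0, meta={"kind": "external"})
    return mesh, G.FiberField(np.asarray(lon, float))


# --- Purkinje tree -----------------------------------------------------------


def write_tree_json(tree: P.PurkinjeTree, path,
                    tree_lat: np.ndarray | None = None) -> None:
    data = {
        "nodes": tree.nodes.tolist(),
        "edges": [[int(a), int(b), int(c), int(f), bool(k)]
                  for a, b, c, f, k in zip(tree.edge_a, tree.edge_b,
                                           tree.edge_class, tree.edge_fascicle,
                                           tree.conductive)],
        "his_root": int(tree.his_root),
        "fascicle_end_nodes": {str(k): int(v)
                               for k, v in tree.fascicle_end_nodes.items()},
        "pmjs": [[int(t), int(m), float(a), float(r)]
                 for t, m, a, r in zip(tree.pmj_tree_nodes, tree.pmj_mesh_nodes,
                                       tree.pmj_anterograde,
                                       tree.pmj_retrograde)],
        "node_mesh_vertex": (tree.node_mesh_vertex.tolist()
                             if tree.node_mesh_vertex is not None else None),
        "block_edge": tree.block_edge,
        "hbp_node": tree.hbp_node,
        "lbbp_node": tree.lbbp_node,
    }
    if tree_lat is not None:
        data["lat_ms"] = [None if not np.isfinite(t) else float(t)
                          for t in tree_lat]
    Path(path).write_text(json.dumps(data))


def read_tree_json(path) -> P.PurkinjeTree:
    data = json.loads(Path(path).read_text())
    edges = np.asarray(data["edges"], object)
    return P.PurkinjeTree(
        nodes=np.asarray(data["nodes"], float),
        edge_a=np.asarray([e[0] for e in data["edges"]], np.int64),
        edge_b=np.asarray([e[1] for e in data["edges"]], np.int64),
        edge_class=np.asarray([e[2] for e in data["edges"]], np.int32),
        edge_fascicle=np.asarray([e[3] for e in data["edges"]], np.int32),
        conductive=np.asarray([e[4] for e in data["edges"]], bool),
        his_root=int(data["his_root"]),
        fascicle_end_nodes={int(k): int(v)
                            for k, v in data["fascicle_end_nodes"].items()},
        pmj_tree_nodes=np.asarray([p[0] for p in data["pmjs"]], np.int64),
        pmj_mesh_nodes=np.asarray([p[1] for p in data["pmjs"]], np.int64),
        pmj_anterograde=np.asarray([p[2] for p in data["pmjs"]], float),
        pmj_retrograde=np.asarray([p[3] for p in data["pmjs"]], float),
        node_mesh_vertex=(None if data.get("node_mesh_vertex") is None
                          else np.asarray(data["node_mesh_vertex"], np.int64)),
        block_edge=data.get("block_edge"),
        hbp_node=data.get("hbp_node"),
        lbbp_node=data.get("lbbp_node"))


def write_tree_vtk(tree: P.PurkinjeTree, path) -> None:
    """Legacy-VTK polyline export of the tree for visualization."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nHis-Purkinje tree\nASCII\n"
                "DATASET POLYDATA\n")
        f.write(f"POINTS {tree.n_nodes} double\n")
        for x, y, z in tree.nodes:
            f.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        m = tree.n_edges
        f.write(f"LINES {m} {3 * m}\n")
        for a, b in zip(tree.edge_a, tree.edge_b):
            f.write(f"2 {a} {b}\n")
        f.write(f"CELL_DATA {m}\nSCALARS edge_class int 1\n"
                "LOOKUP_TABLE default\n")
        f.write("\n".join(str(int(c)) for c in tree.edge_class) + "\n")
        f.write("SCALARS fascicle int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(c)) for c in tree.edge_fascicle) + "\n")


def write_activation_vtu(mesh: G.LabeledMesh, lat: np.ndarray, path,
                         fibers: G.FiberField | None = None) -> None:
    """Mesh VTU with the nodal activation map as point data ``LAT_ms``."""
    safe = np.where(np.isfinite(lat), lat, -1.0)
    write_vtu(mesh, path, fibers=fibers, point_data={"LAT_ms": safe})
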