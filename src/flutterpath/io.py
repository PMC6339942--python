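"""Surface-mesh I/O in plain-text dialects (VTK legacy ASCII, OFF, PLY, STL).

VTK legacy files carry per-node and per-triangle attribute arrays
(``fiber``, ``region``, ``conductive`` plus arbitrary result fields) and are
readable by standard visualization tools.  OFF/PLY/STL carry geometry only.
Region labels are encoded as integer codes in the file with the code table
stored on the VTK title line.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from .mesh import MeshError, TriangularSurfaceMesh

__all__ = ["read_mesh", "write_mesh"]

_REGION_SEP = "|"


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("vtk", "off", "ply", "stl"):
        return ext
    raise ValueError(f"cannot infer mesh format from {path!r}; pass format=")


def write_mesh(
    mesh: TriangularSurfaceMesh,
    path: str,
    point_fields: Mapping[str, np.ndarray] | None = None,
    cell_fields: Mapping[str, np.ndarray] | None = None,
    fmt: str | None = None,
) -> None:
    """Write a mesh plus named per-node / per-triangle arrays.

    Attribute arrays are only supported by the VTK dialect; requesting them
    with another format raises.  Field-length mismatches raise with the
    offending field named.
    """
    fmt = _detect_format(path, fmt)
    point_fields = dict(point_fields or {})
    cell_fields = dict(cell_fields or {})
    for name, arr in point_fields.items():
        if len(np.asarray(arr)) != mesh.n_nodes:
            raise ValueError(f"point field {name!r} has length {len(arr)}, expected {mesh.n_nodes}")
    for name, arr in cell_fields.items():
        if len(np.asarray(arr)) != mesh.n_triangles:
            raise ValueError(f"cell field {name!r} has length {len(arr)}, expected {mesh.n_triangles}")

    if fmt == "vtk":
        _write_vtk(mesh, path, point_fields, cell_fields)
    elif fmt in ("off", "ply", "stl"):
        if point_fields or cell_fields:
            raise ValueError(f"{fmt} cannot store attribute arrays; use vtk")
        {"off": _write_off, "ply": _write_ply, "stl": _write_stl}[fmt](mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def read_mesh(path: str, fmt: str | None = None, with_fields: bool = False):
    """Read and validate a triangle-only surface mesh.

    Returns the mesh, or ``(mesh, point_fields, cell_fields)`` when
    ``with_fields`` is true.  Missing fiber data marks the mesh isotropic;
    missing conductive flags default to all-conductive.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "vtk":
        mesh, pf, cf = _read_vtk(path)
    elif fmt == "off":
        mesh, pf, cf = _read_off(path), {}, {}
    elif fmt == "ply":
        mesh, pf, cf = _read_ply(path), {}, {}
    elif fmt == "stl":
        mesh, pf, cf = _read_stl(path), {}, {}
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    mesh.validate()
    return (mesh, pf, cf) if with_fields else mesh


# ----------------------------------------------------------------------
# VTK legacy ASCII (POLYDATA)
def _write_vtk(mesh, path, point_fields, cell_fields):
    regions = sorted({str(r) for r in mesh.region})
    code = {r: i for i, r in enumerate(regions)}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"flutterpath regions={_REGION_SEP.join(regions)}\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")

        if point_fields:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            _write_data_arrays(f, point_fields)

        cf = dict(cell_fields)
        cf.setdefault("region", np.array([code[str(r)] for r in mesh.region]))
        cf.setdefault("conductive", mesh.conductive.astype(int))
        if mesh.fiber is not None:
            cf.setdefault("fiber", mesh.fiber)
        f.write(f"CELL_DATA {mesh.n_triangles}\n")
        _write_data_arrays(f, cf)


def _write_data_arrays(f, fields):
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            f.write(f"VECTORS {name} double\n")
            for v in arr:
                f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        else:
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in arr.astype(float).ravel():
                f.write(f"{v:.17g}\n")


def _read_vtk(path):
    with open(path) as f:
        tokens_lines = f.readlines()
    title = tokens_lines[1].strip() if len(tokens_lines) > 1 else ""
    regions = None
    if "regions=" in title:
        regions = title.split("regions=", 1)[1].split(_REGION_SEP)

    # token stream after the 4 header lines
    words: list[str] = []
    for ln in tokens_lines[3:]:
        words.extend(ln.split())
    pos = 0

    def take(n):
        nonlocal pos
        out = words[pos : pos + n]
        pos += n
        return out

    nodes = triangles = None
    point_fields: dict[str, np.ndarray] = {}
    cell_fields: dict[str, np.ndarray] = {}
    target = None
    while pos < len(words):
        kw = words[pos].upper()
        if kw == "DATASET":
            take(2)
        elif kw == "POINTS":
            _, n, _ = take(3)
            n = int(n)
            nodes = np.array(take(3 * n), dtype=float).reshape(n, 3)
        elif kw in ("POLYGONS", "CELLS"):
            _, m, total = take(3)
            m, total = int(m), int(total)
            raw = take(total)
            tris = []
            i = 0
            cell = 0
            while i < len(raw):
                k = int(raw[i])
                if k != 3:
                    raise MeshError(f"cell {cell} has {k} vertices; only triangles are supported")
                tris.append([int(raw[i + 1]), int(raw[i + 2]), int(raw[i + 3])])
                i += k + 1
                cell += 1
            triangles = np.array(tris, dtype=np.int64)
        elif kw == "CELL_TYPES":
            _, m = take(2)
            types = take(int(m))
            for ci, t in enumerate(types):
                if int(t) != 5:
                    raise MeshError(f"cell {ci} has VTK type {t}; only triangles (5) are supported")
        elif kw == "POINT_DATA":
            take(2)
            target = point_fields
        elif kw == "CELL_DATA":
            take(2)
            target = cell_fields
        elif kw == "SCALARS":
            _, name, _dtype = take(3)
            if pos < len(words) and words[pos].isdigit():
                take(1)  # optional component count
            if pos < len(words) and words[pos].upper() == "LOOKUP_TABLE":
                take(2)
            n = len(nodes) if target is point_fields else len(triangles)
            target[name] = np.array(take(n), dtype=float)
        elif kw == "VECTORS":
            _, name, _dtype = take(3)
            n = len(nodes) if target is point_fields else len(triangles)
            target[name] = np.array(take(3 * n), dtype=float).reshape(n, 3)
        else:
            pos += 1

    if nodes is None or triangles is None:
        raise MeshError(f"{path}: missing POINTS or POLYGONS section")

    fiber = cell_fields.pop("fiber", None)
    conductive = cell_fields.pop("conductive", None)
    region_codes = cell_fields.pop("region", None)
    region = None
    if region_codes is not None and regions is not None:
        region = np.array([regions[int(c)] for c in region_codes], dtype=object)
    mesh = TriangularSurfaceMesh(
        nodes=nodes,
        triangles=triangles,
        fiber=fiber,
        region=region,
        conductive=None if conductive is None else conductive.astype(bool),
    )
    return mesh, point_fields, cell_fields


# ----------------------------------------------------------------------
# geometry-only dialects
def _write_off(mesh, path):
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_nodes} {mesh.n_triangles} 0\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_off(path):
    with open(path) as f:
        words = f.read().split()
    if words[0] != "OFF":
        raise MeshError(f"{path}: not an OFF file")
    nv, nf = int(words[1]), int(words[2])
    pos = 4
    nodes = np.array(words[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for ci in range(nf):
        k = int(words[pos])
        if k != 3:
            raise MeshError(f"cell {ci} has {k} vertices; only triangles are supported")
        tris.append([int(w) for w in words[pos + 1 : pos + 4]])
        pos += k + 1
    return TriangularSurfaceMesh(nodes=nodes, triangles=np.array(tris, dtype=np.int64))


def _write_ply(mesh, path):
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {mesh.n_nodes}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write(f"element face {mesh.n_triangles}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_ply(path):
    with open(path) as f:
        lines = [ln.strip() for ln in f]
    if lines[0] != "ply" or "ascii" not in lines[1]:
        raise MeshError(f"{path}: only ascii PLY is supported")
    nv = nf = 0
    i = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            nv = int(ln.split()[-1])
        elif ln.startswith("element face"):
            nf = int(ln.split()[-1])
        elif ln == "end_header":
            break
    body = lines[i + 1 :]
    nodes = np.array([body[j].split()[:3] for j in range(nv)], dtype=float)
    tris = []
    for ci in range(nf):
        parts = body[nv + ci].split()
        if int(parts[0]) != 3:
            raise MeshError(f"cell {ci} has {parts[0]} vertices; only triangles are supported")
        tris.append([int(p) for p in parts[1:4]])
    return TriangularSurfaceMesh(nodes=nodes, triangles=np.array(tris, dtype=np.int64))


def _write_stl(mesh, path):
    a, b, c = mesh.triangle_points()
    normals = mesh.triangle_normals()
    with open(path, "w") as f:
        f.write("solid flutterpath\n")
        for i in range(mesh.n_triangles):
            n = normals[i]
            f.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n outer loop\n")
            for p in (a[i], b[i], c[i]):
                f.write(f"  vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            f.write(" endloop\nendfacet\n")
        f.write("endsolid flutterpath\n")


def _read_stl(path):
    verts = []
    with open(path) as f:
        for ln in f:
            parts = ln.split()
            if parts and parts[0] == "vertex":
                verts.append([float(x) for x in parts[1:4]])
    verts = np.array(verts, dtype=float)
    if len(verts) % 3:
        raise MeshError(f"{path}: malformed STL (vertex count not a multiple of 3)")
    # merge duplicate vertices (exact on the printed precision)
    uniq, inverse = np.unique(np.round(verts, 6), axis=0, return_inverse=True)
    triangles = inverse.reshape(-1, 3).astype(np.int64)
    return TriangularSurfaceMesh(nodes=uniq, triangles=triangles)
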