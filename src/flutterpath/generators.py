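"""Synthetic surface geometries for benchmark scenarios.

Generators produce near-uniform triangulations: planar sheets with optional
slow-conduction disks, flat annular bands, closed cylinders, and sphere-like
chamber surrogates with orifices and ablation-lesion bands (with optional
gaps).  Lesions only flip the per-triangle conductive flag; they never alter
topology, so re-opening a gap is a local flag edit.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .mesh import Annotation, MeshError, TriangularSurfaceMesh

__all__ = [
    "generate_planar_sheet",
    "generate_annulus",
    "generate_cylinder",
    "generate_atrial_surrogate",
    "apply_annotations",
]


# ----------------------------------------------------------------------
# helpers
def _strip_triangulate(row_a: np.ndarray, row_b: np.ndarray, off_a: int, off_b: int) -> list[tuple[int, int, int]]:
    """Triangulate the band between two x-sorted point rows.

    Greedy advance: at each step close the triangle with the shorter new
    diagonal, which yields a Delaunay-like strip for staggered rows.
    """
    tris = []
    i, j = 0, 0
    na, nb = len(row_a), len(row_b)
    while i < na - 1 or j < nb - 1:
        if i == na - 1:
            tris.append((off_a + i, off_b + j, off_b + j + 1))
            j += 1
        elif j == nb - 1:
            tris.append((off_a + i, off_b + j, off_a + i + 1))
            i += 1
        else:
            da = np.linalg.norm(row_a[i + 1] - row_b[j])
            db = np.linalg.norm(row_b[j + 1] - row_a[i])
            if da <= db:
                tris.append((off_a + i, off_b + j, off_a + i + 1))
                i += 1
            else:
                tris.append((off_a + i, off_b + j, off_b + j + 1))
                j += 1
    return tris


def _tangentialize(fiber: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Project fiber vectors into their triangle planes and normalize."""
    f = fiber - np.einsum("ij,ij->i", fiber, normals)[:, None] * normals
    n = np.linalg.norm(f, axis=1)
    # fall back to an arbitrary in-plane direction where the projection vanishes
    bad = n < 1e-8
    if bad.any():
        alt = np.cross(normals[bad], np.array([0.0, 0.0, 1.0]))
        alt_n = np.linalg.norm(alt, axis=1)
        weak = alt_n < 1e-8
        alt[weak] = np.cross(normals[bad][weak], np.array([1.0, 0.0, 0.0]))
        f[bad] = alt
        n[bad] = np.linalg.norm(alt, axis=1)
    return f / n[:, None]


# ----------------------------------------------------------------------
def generate_planar_sheet(
    width: float,
    height: float,
    edge_length: float,
    annotations: Sequence[Annotation] = (),
) -> TriangularSurfaceMesh:
    """Near-uniform triangulated rectangle in the z=0 plane.

    Rows form a staggered (near-equilateral) lattice.  Triangles whose
    centroid falls inside a ``slow_zone`` disk get that zone's region label.
    Fiber direction defaults to +x.
    """
    if not (width > 2 * edge_length and height > 2 * edge_length):
        raise ValueError("sheet dimensions must exceed 2 * edge_length")
    for ann in annotations:
        if ann.kind == "slow_zone":
            cx, cy = float(ann.center[0]), float(ann.center[1])
            r = float(ann.radius)
            if not (r <= cx <= width - r and r <= cy <= height - r):
                raise ValueError("slow_zone disk extends outside the sheet")

    row_h = edge_length * math.sqrt(3.0) / 2.0
    n_rows = max(2, round(height / row_h))
    n_cols = max(2, round(width / edge_length))
    dy = height / n_rows
    dx = width / n_cols

    rows: list[np.ndarray] = []
    offsets: list[int] = []
    points: list[np.ndarray] = []
    for j in range(n_rows + 1):
        y = j * dy
        if j % 2 == 0:
            xs = np.arange(n_cols + 1) * dx
        else:
            xs = np.concatenate([[0.0], (np.arange(n_cols) + 0.5) * dx, [width]])
        row = np.column_stack([xs, np.full(len(xs), y), np.zeros(len(xs))])
        offsets.append(sum(len(r) for r in rows))
        rows.append(row)
        points.append(row)
    nodes = np.concatenate(points, axis=0)

    tris: list[tuple[int, int, int]] = []
    for j in range(n_rows):
        tris.extend(_strip_triangulate(rows[j], rows[j + 1], offsets[j], offsets[j + 1]))
    triangles = np.array(tris, dtype=np.int64)

    fiber = np.tile(np.array([1.0, 0.0, 0.0]), (len(triangles), 1))
    mesh = TriangularSurfaceMesh(nodes=nodes, triangles=triangles, fiber=fiber)
    apply_annotations(mesh, annotations)
    mesh.validate()
    return mesh


def generate_annulus(
    r_mean: float,
    tube_half_width: float,
    edge_length: float,
    region: str = "default",
) -> TriangularSurfaceMesh:
    """Flat annular band in the z=0 plane centered at the origin.

    Euler characteristic 0, two boundary loops; the inner rim is the shortest
    non-contractible cycle.  Fibers run circumferentially.
    """
    if not (r_mean > tube_half_width > edge_length):
        raise ValueError("require r_mean > tube_half_width > edge_length")
    nodes, triangles = _ring_lattice(
        r_inner=r_mean - tube_half_width,
        r_outer=r_mean + tube_half_width,
        circ=2 * math.pi * r_mean,
        edge_length=edge_length,
    )

    def pos(r, theta, _):
        return np.array([r * math.cos(theta), r * math.sin(theta), 0.0])

    nodes = np.array([pos(*n) for n in nodes])
    triangles = np.array(triangles, dtype=np.int64)
    centro = nodes[triangles].mean(axis=1)
    fiber = np.column_stack([-centro[:, 1], centro[:, 0], np.zeros(len(centro))])
    fiber /= np.linalg.norm(fiber, axis=1)[:, None]
    mesh = TriangularSurfaceMesh(
        nodes=nodes,
        triangles=triangles,
        fiber=fiber,
        region=np.full(len(triangles), region, dtype=object),
    )
    mesh.validate()
    return mesh


def _ring_lattice(r_inner: float, r_outer: float, circ: float, edge_length: float):
    """Staggered lattice of (radial_coord, angle, ring) tuples plus triangles.

    Shared by the annulus (radial coordinate = radius) and the cylinder
    (radial coordinate = height).  Rings all carry the same point count so
    the strip closes; alternate rings are staggered by half an angular step.
    """
    n_theta = max(8, round(circ / edge_length))
    row_h = edge_length * math.sqrt(3.0) / 2.0
    n_rings = max(1, round((r_outer - r_inner) / row_h))
    dr = (r_outer - r_inner) / n_rings
    dtheta = 2 * math.pi / n_theta

    coords = []
    for j in range(n_rings + 1):
        r = r_inner + j * dr
        shift = 0.5 * dtheta if j % 2 else 0.0
        for i in range(n_theta):
            coords.append((r, i * dtheta + shift, j))
    tris = []
    for j in range(n_rings):
        a0 = j * n_theta
        b0 = (j + 1) * n_theta
        for i in range(n_theta):
            i1 = (i + 1) % n_theta
            if j % 2 == 0:
                # upper ring staggered forward by half a step
                tris.append((a0 + i, a0 + i1, b0 + i))
                tris.append((a0 + i1, b0 + i1, b0 + i))
            else:
                tris.append((a0 + i, a0 + i1, b0 + i1))
                tris.append((a0 + i, b0 + i1, b0 + i))
    return coords, tris


def generate_cylinder(
    radius: float,
    length: float,
    edge_length: float,
    region: str = "default",
) -> TriangularSurfaceMesh:
    """Open-ended cylindrical tube along z, topologically an annulus."""
    if not (radius > edge_length and length > edge_length):
        raise ValueError("radius and length must exceed edge_length")
    coords, triangles = _ring_lattice(
        r_inner=0.0, r_outer=length, circ=2 * math.pi * radius, edge_length=edge_length
    )
    nodes = np.array(
        [[radius * math.cos(t), radius * math.sin(t), z] for z, t, _ in coords]
    )
    triangles = np.array(triangles, dtype=np.int64)
    centro = nodes[triangles].mean(axis=1)
    fiber = np.column_stack([-centro[:, 1], centro[:, 0], np.zeros(len(centro))])
    fiber /= np.linalg.norm(fiber, axis=1)[:, None]
    mesh = TriangularSurfaceMesh(
        nodes=nodes,
        triangles=triangles,
        fiber=fiber,
        region=np.full(len(triangles), region, dtype=object),
    )
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
def _icosphere(radius: float, subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = [v for v in verts]

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key in cache:
                return cache[key]
            m = vlist[a] + vlist[b]
            m /= np.linalg.norm(m)
            vlist.append(m)
            cache[key] = len(vlist) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return verts * radius, faces


def generate_atrial_surrogate(
    radius: float = 25.0,
    orifices: Sequence[dict] = (),
    annotations: Sequence[Annotation] = (),
    subdivisions: int = 4,
    region: str = "default",
) -> TriangularSurfaceMesh:
    """Sphere-like chamber surrogate with orifices and lesion annotations.

    Parameters
    ----------
    orifices : sequence of dicts
        Each with ``direction`` (3-vector from the center) and ``radius``
        (mm, spherical-cap opening radius measured along the surface).
        Triangles whose centroid falls inside the cap are removed.
    annotations : sequence of Annotation
        ``lesion_line`` polylines are rendered as bands of non-conductive
        triangles; ``lesion_gap`` entries re-open a stated arc-length
        interval of a previously listed line.
    """
    dirs = []
    for o in orifices:
        d = np.asarray(o["direction"], dtype=float)
        dirs.append((d / np.linalg.norm(d), float(o["radius"]) / radius))
    for (d1, a1), (d2, a2) in (
        (dirs[i], dirs[j]) for i in range(len(dirs)) for j in range(i + 1, len(dirs))
    ):
        if math.acos(np.clip(d1 @ d2, -1, 1)) < a1 + a2:
            raise ValueError("overlapping orifices")

    verts, faces = _icosphere(radius, subdivisions)
    centroids = verts[faces].mean(axis=1)
    keep = np.ones(len(faces), dtype=bool)
    for d, ang in dirs:
        cen_dir = centroids / np.linalg.norm(centroids, axis=1)[:, None]
        keep &= np.arccos(np.clip(cen_dir @ d, -1, 1)) > ang
    faces = faces[keep]

    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = verts[used]
    triangles = remap[faces]

    normals = np.cross(
        nodes[triangles[:, 1]] - nodes[triangles[:, 0]],
        nodes[triangles[:, 2]] - nodes[triangles[:, 0]],
    )
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    # fibers: local "east" direction (around z), arbitrary but tangent
    east = np.cross(np.array([0.0, 0.0, 1.0]), nodes[triangles].mean(axis=1))
    fiber = _tangentialize(east, normals)

    mesh = TriangularSurfaceMesh(
        nodes=nodes,
        triangles=triangles,
        fiber=fiber,
        region=np.full(len(triangles), region, dtype=object),
    )
    apply_annotations(mesh, annotations)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
def _polyline_distance(points: np.ndarray, polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each point to a polyline plus arc-length of the foot."""
    best = np.full(len(points), np.inf)
    arc = np.zeros(len(points))
    s0 = 0.0
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        L = np.linalg.norm(ab)
        if L < 1e-12:
            continue
        t = np.clip((points - a) @ ab / (L * L), 0.0, 1.0)
        foot = a + t[:, None] * ab
        d = np.linalg.norm(points - foot, axis=1)
        closer = d < best
        best[closer] = d[closer]
        arc[closer] = s0 + t[closer] * L
        s0 += L
    return best, arc


def apply_annotations(mesh: TriangularSurfaceMesh, annotations: Sequence[Annotation]) -> None:
    """Apply slow zones / lesion lines / lesion gaps in order, in place."""
    centroids = mesh.triangle_centroids()
    lines: list[Annotation] = []
    for ann in annotations:
        if ann.kind == "slow_zone":
            c = np.asarray(ann.center, dtype=float)
            if len(c) == 2:
                c = np.array([c[0], c[1], 0.0])
            inside = np.linalg.norm(centroids - c, axis=1) <= ann.radius
            mesh.region[inside] = ann.region
            lines.append(ann)
        elif ann.kind == "lesion_line":
            d, _ = _polyline_distance(centroids, ann.polyline)
            mesh.conductive[d <= ann.width / 2.0] = False
            lines.append(ann)
        elif ann.kind == "lesion_gap":
            ref = lines[ann.line_index]
            if ref.kind != "lesion_line":
                raise MeshError("lesion_gap must reference a lesion_line annotation")
            d, s = _polyline_distance(centroids, ref.polyline)
            lo, hi = ann.interval
            reopen = (d <= ref.width / 2.0) & (s >= lo) & (s <= hi)
            mesh.conductive[reopen] = True
            lines.append(ann)
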