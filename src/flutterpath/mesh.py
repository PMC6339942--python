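"""Triangular surface mesh data model and adjacency structures.

All lengths are millimetres.  A mesh is a lumped representation of a thin
conducting wall: geometry lives on the nodes, while electrophysiological
attributes (fiber direction, region label, conductive flag) live on the
triangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MeshError",
    "TriangularSurfaceMesh",
    "Annotation",
    "Adjacency",
    "build_adjacency",
]

DEFAULT_REGION = "default"


class MeshError(ValueError):
    """Raised when a mesh violates the surface-mesh contract."""


@dataclass
class Annotation:
    """Geometric annotation applied to a generated mesh.

    kind: one of ``slow_zone`` (disk, relabels triangles), ``lesion_line``
    (polyline band, sets conductive=False) or ``lesion_gap`` (sub-interval of
    a lesion_line, restores conductivity).
    """

    kind: str
    center: Sequence[float] | None = None
    radius: float | None = None
    polyline: np.ndarray | None = None
    width: float | None = None
    region: str | None = None
    # for lesion_gap: index of the referenced lesion_line annotation and the
    # arc-length sub-interval (mm, along the polyline) to re-open
    line_index: int | None = None
    interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("slow_zone", "lesion_line", "lesion_gap"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.kind == "slow_zone":
            if self.radius is None or self.radius <= 0:
                raise ValueError("slow_zone requires radius > 0")
            if self.center is None:
                raise ValueError("slow_zone requires a center")
            if self.region is None:
                self.region = "slow"
        if self.kind == "lesion_line":
            if self.polyline is None or len(np.asarray(self.polyline)) < 2:
                raise ValueError("lesion_line requires a polyline with >= 2 points")
            if self.width is None or self.width <= 0:
                raise ValueError("lesion_line requires width > 0")
            self.polyline = np.asarray(self.polyline, dtype=float)
        if self.kind == "lesion_gap":
            if self.line_index is None or self.interval is None:
                raise ValueError("lesion_gap must reference a lesion_line and an interval")
            lo, hi = self.interval
            if not hi > lo:
                raise ValueError("lesion_gap interval must be non-empty")


@dataclass
class TriangularSurfaceMesh:
    """Triangle-only surface mesh with per-triangle substrate attributes.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node positions in mm.
    triangles : (M, 3) int array
        Vertex index triples.
    fiber : (M, 3) float array or None
        Unit principal myocyte direction per triangle, tangent to the
        triangle plane.  ``None`` marks an isotropic mesh.
    region : (M,) str array
        Categorical region label per triangle.
    conductive : (M,) bool array
        ``False`` marks ablated / non-conductive triangles.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    fiber: np.ndarray | None = None
    region: np.ndarray | None = None
    conductive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.region is None:
            self.region = np.full(len(self.triangles), DEFAULT_REGION, dtype=object)
        else:
            self.region = np.asarray(self.region, dtype=object)
        if self.conductive is None:
            self.conductive = np.ones(len(self.triangles), dtype=bool)
        else:
            self.conductive = np.asarray(self.conductive, dtype=bool)
        if self.fiber is not None:
            self.fiber = np.asarray(self.fiber, dtype=float)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def is_isotropic(self) -> bool:
        return self.fiber is None

    def triangle_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.triangles
        return self.nodes[t[:, 0]], self.nodes[t[:, 1]], self.nodes[t[:, 2]]

    def triangle_areas(self) -> np.ndarray:
        a, b, c = self.triangle_points()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_normals(self) -> np.ndarray:
        a, b, c = self.triangle_points()
        n = np.cross(b - a, c - a)
        norms = np.linalg.norm(n, axis=1)
        norms[norms == 0] = 1.0
        return n / norms[:, None]

    def triangle_centroids(self) -> np.ndarray:
        a, b, c = self.triangle_points()
        return (a + b + c) / 3.0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise :class:`MeshError` on failure."""
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (M, 3) array")
        t = self.triangles
        if t.size and (t.min() < 0 or t.max() >= self.n_nodes):
            bad = int(np.argwhere((t < 0) | (t >= self.n_nodes))[0, 0])
            raise MeshError(f"triangle {bad} references an invalid node index")
        same = (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        if same.any():
            raise MeshError(f"triangle {int(np.argmax(same))} has repeated vertices")
        areas = self.triangle_areas()
        if (areas < 1e-12).any():
            raise MeshError(f"degenerate (zero-area) triangle {int(np.argmax(areas < 1e-12))}")
        for name, arr, dtype in (
            ("region", self.region, None),
            ("conductive", self.conductive, bool),
        ):
            if len(arr) != self.n_triangles:
                raise MeshError(f"{name} length {len(arr)} != triangle count {self.n_triangles}")
        if self.fiber is not None:
            if self.fiber.shape != (self.n_triangles, 3):
                raise MeshError("fiber must be an (M, 3) array")
            norms = np.linalg.norm(self.fiber, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise MeshError(f"fiber vector {int(np.argmax(np.abs(norms - 1) > 1e-9))} is not unit")
            normals = self.triangle_normals()
            out_of_plane = np.abs(np.einsum("ij,ij->i", self.fiber, normals))
            if (out_of_plane > 1.0000001e-6).any():
                raise MeshError(
                    f"fiber vector {int(np.argmax(out_of_plane > 1.0000001e-6))} "
                    "is not tangent to its triangle plane"
                )
        # edge-manifold: each edge shared by at most two triangles
        edges = _edge_array(self.triangles)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if (counts > 2).any():
            e = uniq[int(np.argmax(counts > 2))]
            raise MeshError(f"non-manifold edge ({int(e[0])}, {int(e[1])})")

    def copy(self) -> "TriangularSurfaceMesh":
        return TriangularSurfaceMesh(
            nodes=self.nodes.copy(),
            triangles=self.triangles.copy(),
            fiber=None if self.fiber is None else self.fiber.copy(),
            region=self.region.copy(),
            conductive=self.conductive.copy(),
        )


def _edge_array(triangles: np.ndarray) -> np.ndarray:
    """All triangle edges as sorted (lo, hi) pairs, one row per half-edge."""
    e = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]], axis=0
    )
    return np.sort(e, axis=1)


@dataclass
class Adjacency:
    """Topology lookups derived from a mesh.

    ``edges`` is an (E, 2) array of sorted node pairs; ``edge_tris`` maps each
    edge to its incident triangle indices; ``traversable`` marks edges with at
    least one conductive incident triangle.
    """

    edges: np.ndarray
    edge_lengths: np.ndarray
    edge_tris: list[list[int]]
    traversable: np.ndarray
    node_neighbors: list[np.ndarray]
    node_triangles: list[np.ndarray]
    edge_index: dict[tuple[int, int], int] = field(repr=False, default_factory=dict)

    def neighbors(self, i: int) -> np.ndarray:
        return self.node_neighbors[i]

    def edge_id(self, i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        return self.edge_index[key]

    def traversable_csr(self, weights: np.ndarray | None = None):
        """Sparse symmetric graph over traversable edges (scipy CSR).

        ``weights`` defaults to edge lengths.
        """
        from scipy.sparse import csr_matrix

        w = self.edge_lengths if weights is None else np.asarray(weights, dtype=float)
        keep = self.traversable
        e = self.edges[keep]
        w = w[keep]
        n = len(self.node_neighbors)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.concatenate([w, w])
        return csr_matrix((data, (rows, cols)), shape=(n, n))


def build_adjacency(mesh: TriangularSurfaceMesh) -> Adjacency:
    """Build node/edge/triangle adjacency for a validated mesh.

    Edges whose incident triangles are all non-conductive are marked
    non-traversable, so graph searches cannot cross ablation lesions.
    """
    tri = mesh.triangles
    half = _edge_array(tri)
    tri_of_half = np.tile(np.arange(len(tri)), 3)
    edges, inverse = np.unique(half, axis=0, return_inverse=True)

    edge_tris: list[list[int]] = [[] for _ in range(len(edges))]
    for h, e in enumerate(inverse):
        edge_tris[e].append(int(tri_of_half[h]))

    lengths = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1)
    cond = mesh.conductive
    traversable = np.array([any(cond[t] for t in ts) for ts in edge_tris], dtype=bool)

    nbrs: list[set[int]] = [set() for _ in range(mesh.n_nodes)]
    for (a, b) in edges:
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))
    node_neighbors = [np.array(sorted(s), dtype=np.int64) for s in nbrs]

    node_tris: list[list[int]] = [[] for _ in range(mesh.n_nodes)]
    for t, (a, b, c) in enumerate(tri):
        node_tris[a].append(t)
        node_tris[b].append(t)
        node_tris[c].append(t)
    node_triangles = [np.array(ts, dtype=np.int64) for ts in node_tris]

    edge_index = {(int(a), int(b)): k for k, (a, b) in enumerate(edges)}
    return Adjacency(
        edges=edges,
        edge_lengths=lengths,
        edge_tris=edge_tris,
        traversable=traversable,
        node_neighbors=node_neighbors,
        node_triangles=node_triangles,
        edge_index=edge_index,
    )
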