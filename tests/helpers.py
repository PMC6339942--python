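"""Independent oracles used to cross-check the solvers.

These deliberately avoid the package's fast-marching machinery: travel times
come from Dijkstra searches over an enriched edge graph (mesh edges plus
straight chords between nodes up to three hops apart), which bounds the
metrication error well below the solver tolerances under test.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


def chord_graph(mesh, adjacency, speed_mm_ms: float, max_ring: int = 3) -> csr_matrix:
    """Travel-time graph over mesh edges and straight K-ring chords.

    Valid on flat convex meshes with homogeneous isotropic speed (chords are
    straight lines in the plane).
    """
    n = mesh.n_nodes
    pos = mesh.nodes
    rows, cols, data = [], [], []
    for i in range(n):
        ring = {i}
        frontier = {i}
        for _ in range(max_ring):
            nxt = set()
            for u in frontier:
                nxt.update(int(v) for v in adjacency.node_neighbors[u])
            nxt -= ring
            ring |= nxt
            frontier = nxt
        for j in ring:
            if j == i:
                continue
            w = np.linalg.norm(pos[j] - pos[i]) / speed_mm_ms
            rows.append(i)
            cols.append(j)
            data.append(w)
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def oracle_times(mesh, adjacency, source: int, speed_mm_ms: float, max_ring: int = 3):
    g = chord_graph(mesh, adjacency, speed_mm_ms, max_ring)
    return dijkstra(g, indices=source, directed=False)


def shortest_noncontractible_cycle(mesh, adjacency) -> float:
    """Length (mm) of the shortest cycle around an annulus-like hole.

    Cuts the edge graph along the positive-x half plane crossing y = 0 and
    closes each removed edge by a shortest path in the cut graph.
    """
    edges = adjacency.edges
    lengths = adjacency.edge_lengths
    pos = mesh.nodes
    crossing = []
    keep = np.ones(len(edges), dtype=bool)
    for k, (a, b) in enumerate(edges):
        ya, yb = pos[a, 1], pos[b, 1]
        if (pos[a, 0] + pos[b, 0]) > 0 and (
            (ya > 0 and yb <= 0) or (yb > 0 and ya <= 0) or (ya == 0 and yb == 0)
        ):
            crossing.append(k)
            keep[k] = False
    e = edges[keep]
    w = lengths[keep]
    n = mesh.n_nodes
    g = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    best = np.inf
    sources = sorted({int(edges[k, 0]) for k in crossing})
    dists = dijkstra(g, indices=sources, directed=False)
    for k in crossing:
        a, b = int(edges[k, 0]), int(edges[k, 1])
        row = sources.index(a)
        best = min(best, dists[row, b] + lengths[k])
    return float(best)
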