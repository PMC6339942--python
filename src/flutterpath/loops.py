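"""Reentrant-loop candidate detection from wavefront collisions.

A collision is an adjacent node pair whose unit activation vectors nearly
oppose: ``||a_i/|a_i| + a_j/|a_j||| < 0.99`` (unit vectors at an angle above
~121 degrees).  Loops are assembled by back-tracing both collision nodes to
the stimulus along stored predecessors, their round-trip time (RTT) is the
fixed point of the restitution-aware travel-time sum, and the wavelength
condition ``max_i ERP_i(RTT) < RTT`` decides whether a loop can sustain
reentry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eikonal import ActivationField, ConductionTensorField
from .mesh import Adjacency, TriangularSurfaceMesh
from .restitution import SubstrateConfig

__all__ = [
    "CollisionSite",
    "Loop",
    "detect_collisions",
    "cluster_collisions",
    "trace_half",
    "assemble_loop",
    "compute_rtt",
    "check_wavelength",
    "RttError",
]

COLLISION_THRESHOLD = 0.99


@dataclass(frozen=True)
class CollisionSite:
    """Adjacent node pair (i < j) whose activation directions oppose."""

    i: int
    j: int
    collision_time: float


@dataclass
class Loop:
    """Ordered cyclic node sequence (closure between last and first implied)."""

    nodes: list[int]
    rtt: float | None = None
    wl_ok: bool | None = None
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)
    # the two stimulus-to-collision half traces, kept for pruning
    half_i: list[int] | None = None
    half_j: list[int] | None = None

    def edges(self) -> list[tuple[int, int]]:
        n = self.nodes
        return [(n[q], n[(q + 1) % len(n)]) for q in range(len(n))]

    def __len__(self) -> int:
        return len(self.nodes)


class RttError(RuntimeError):
    """Round-trip-time fixed point failed to converge."""


def detect_collisions(field: ActivationField, adjacency: Adjacency) -> list[CollisionSite]:
    """All de-duplicated neighbor pairs satisfying the collision condition.

    Stimulus nodes (no predecessor) are excluded.
    """
    vec = field.activation_vectors()
    norms = np.linalg.norm(vec, axis=1)
    ok = (field.pred >= 0) & (norms > 0) & np.isfinite(field.times)
    if not ok.any():
        return []
    unit = np.zeros_like(vec)
    unit[ok] = vec[ok] / norms[ok, None]

    e = adjacency.edges
    both = ok[e[:, 0]] & ok[e[:, 1]] & adjacency.traversable
    s = unit[e[both, 0]] + unit[e[both, 1]]
    hit = np.linalg.norm(s, axis=1) < COLLISION_THRESHOLD
    pairs = e[both][hit]
    times = np.maximum(field.times[pairs[:, 0]], field.times[pairs[:, 1]])
    sites = [
        CollisionSite(int(a), int(b), float(t))
        for (a, b), t in zip(pairs, times)
    ]
    sites.sort(key=lambda s: (s.i, s.j))
    return sites


def cluster_collisions(sites: list[CollisionSite], adjacency: Adjacency) -> list[list[CollisionSite]]:
    """Group collision sites into connected clusters.

    Two sites are connected when they share a node or their node pairs are
    mesh neighbors.  Within a cluster the pair with the latest collision time
    seeds the loop ("point of latest activation").
    """
    if not sites:
        return []
    parent = list(range(len(sites)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    node_to_sites: dict[int, list[int]] = {}
    for idx, s in enumerate(sites):
        node_to_sites.setdefault(s.i, []).append(idx)
        node_to_sites.setdefault(s.j, []).append(idx)
    for node, idxs in node_to_sites.items():
        for other in adjacency.neighbors(node):
            for oidx in node_to_sites.get(int(other), ()):
                union(idxs[0], oidx)
        for idx in idxs[1:]:
            union(idxs[0], idx)

    groups: dict[int, list[CollisionSite]] = {}
    for idx, s in enumerate(sites):
        groups.setdefault(find(idx), []).append(s)
    clusters = list(groups.values())
    clusters.sort(key=lambda g: (g[0].i, g[0].j))
    return clusters


def seed_site(cluster: list[CollisionSite]) -> CollisionSite:
    """Latest-activation site of a cluster (deterministic tie-break)."""
    return max(cluster, key=lambda s: (s.collision_time, -s.i, -s.j))


def trace_half(field: ActivationField, start: int) -> list[int]:
    """Predecessor path from ``start`` back to a stimulus node.

    Activation times are strictly decreasing along the returned path.
    """
    if not math.isfinite(field.times[start]):
        raise ValueError(f"node {start} was never reached")
    path = [int(start)]
    seen = {int(start)}
    node = int(start)
    while node not in field.stimulus_nodes:
        p = int(field.pred[node])
        if p < 0 or p in seen:
            raise RuntimeError(f"broken predecessor chain at node {node}")
        if not field.times[p] < field.times[node]:
            raise RuntimeError(
                f"non-decreasing trace: t({p})={field.times[p]} >= t({node})={field.times[node]}"
            )
        path.append(p)
        seen.add(p)
        node = p
    return path


def assemble_loop(site: CollisionSite, field: ActivationField) -> Loop:
    """Close a loop through a collision site via the two stimulus traces.

    When the two traces terminate on different nodes of one multi-node
    stimulus, the loop is joined through the stimulus set (the two stimulus
    end nodes become adjacent loop entries by construction of the stimulus).
    """
    ti = trace_half(field, site.i)  # [i, ..., stim]
    tj = trace_half(field, site.j)
    half_i = list(reversed(ti))  # [stim, ..., i]
    half_j = list(reversed(tj))  # [stim, ..., j]
    nodes = half_i + list(reversed(half_j))
    if half_i[0] == half_j[0]:
        nodes = half_i + list(reversed(half_j[1:]))  # drop duplicated stimulus
    return Loop(
        nodes=nodes,
        provenance={"stimulus": half_i[0], "collision": (site.i, site.j)},
        half_i=half_i,
        half_j=half_j,
    )


def _edge_inv_speed(
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    adjacency: Adjacency,
    a: int,
    b: int,
    bcl: float,
) -> float:
    """Inverse directional speed (ms/mm) of edge (a, b) at the given BCL.

    Averaged over the conductive incident triangles; direction-symmetric, so
    RTT is invariant under loop rotation and reversal.
    """
    d = mesh.nodes[b] - mesh.nodes[a]
    L = np.linalg.norm(d)
    u = d / L
    eid = adjacency.edge_id(a, b)
    speeds = []
    for t in adjacency.edge_tris[eid]:
        if mesh.conductive[t]:
            speeds.append(tensor_field.directional_speed(t, u, bcl))
    if not speeds:
        raise RttError(f"loop edge ({a}, {b}) crosses only non-conductive triangles")
    return 1.0 / float(np.mean(speeds))


def compute_rtt(
    loop: Loop,
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    cfg: SubstrateConfig,
    adjacency: Adjacency,
    tol: float = 0.5,
    max_iter: int = 50,
) -> float:
    """Fixed point of the restitution-aware loop travel time, in ms.

    Iterates ``rtt <- sum_e length(e) / speed_e(bcl=rtt)`` from the
    long-cycle (BCLmax) speed until the update falls below ``tol`` ms.
    """
    if loop.degenerate or len(loop) < 3:
        raise ValueError("cannot compute RTT of a degenerate loop")
    edges = loop.edges()
    lengths = np.array(
        [np.linalg.norm(mesh.nodes[b] - mesh.nodes[a]) for a, b in edges]
    )
    rtt = cfg.bcl_range[1]
    trace = []
    for _ in range(max_iter):
        inv = np.array(
            [
                _edge_inv_speed(mesh, tensor_field, adjacency, a, b, rtt)
                for a, b in edges
            ]
        )
        new = float(np.dot(lengths, inv))
        trace.append(new)
        if abs(new - rtt) < tol:
            loop.rtt = new
            return new
        rtt = new
    raise RttError(f"RTT fixed point did not converge; iterates: {trace}")


def node_erp(
    mesh: TriangularSurfaceMesh,
    cfg: SubstrateConfig,
    adjacency: Adjacency,
    node: int,
    bcl: float,
) -> float:
    """ERP of a node at the given BCL: max over incident conductive regions."""
    labels = {
        str(mesh.region[t])
        for t in adjacency.node_triangles[node]
        if mesh.conductive[t]
    }
    if not labels:
        labels = {str(mesh.region[t]) for t in adjacency.node_triangles[node]}
    return max(cfg.erp(lbl, bcl) for lbl in labels)


def check_wavelength(
    loop: Loop,
    mesh: TriangularSurfaceMesh,
    cfg: SubstrateConfig,
    adjacency: Adjacency,
) -> bool:
    """Wavelength condition: ``max_i ERP_i(RTT) < RTT``."""
    if loop.rtt is None:
        raise ValueError("compute_rtt must run before check_wavelength")
    worst = max(node_erp(mesh, cfg, adjacency, n, loop.rtt) for n in loop.nodes)
    loop.wl_ok = bool(worst < loop.rtt)
    return loop.wl_ok
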