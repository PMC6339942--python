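"""Anisotropic multifront fast marching on triangular surface meshes.

The activation time field solves the surface eikonal equation
``c * sqrt(grad_t' G grad_t) = 1`` where G has eigenvalues {k, 1, 1} with the
principal eigenvector along the local fiber direction.  The exact point-source
solution of this equation is the geodesic distance under the metric
``G^-1 / c^2``; the solver therefore uses the closed-form two-point
within-triangle update in that metric, falling back to one-point edge updates
when the characteristic leaves the triangle.  Directional speed along a unit
vector u equals ``c * sqrt(u' G u)`` on the tensor eigendirections (fiber:
``c*sqrt(k)``, cross-fiber: ``c``).

No recursive anisotropic correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np

from .mesh import Adjacency, TriangularSurfaceMesh, build_adjacency
from .restitution import SubstrateConfig

__all__ = [
    "ConductionTensorField",
    "ActivationField",
    "build_tensor_field",
    "solve_activation",
]


@dataclass
class ConductionTensorField:
    """Per-triangle conduction tensors and substrate bindings.

    ``ginv`` holds the 6 unique entries (xx, xy, xz, yy, yz, zz) of
    ``G^-1 = (1/k) f f' + (I - f f')`` per triangle.  Base speeds come from
    the bound :class:`SubstrateConfig` through each triangle's region.
    """

    mesh: TriangularSurfaceMesh
    cfg: SubstrateConfig
    ginv: np.ndarray  # (M, 6)
    k: np.ndarray  # (M,)
    region_index: np.ndarray  # (M,) int codes into `regions`
    regions: list[str]

    def G(self, t: int) -> np.ndarray:
        """Full 3x3 anisotropy tensor of triangle t (for inspection/tests)."""
        k = self.k[t]
        if self.mesh.fiber is None or k == 1.0:
            return np.eye(3)
        f = self.mesh.fiber[t]
        return k * np.outer(f, f) + (np.eye(3) - np.outer(f, f))

    def Ginv(self, t: int) -> np.ndarray:
        g = self.ginv[t]
        return np.array(
            [[g[0], g[1], g[2]], [g[1], g[3], g[4]], [g[2], g[4], g[5]]]
        )

    def directional_speed(self, t: int, u: np.ndarray, bcl: float) -> float:
        """Plane-wave speed c*sqrt(u' G u) in mm/ms along unit direction u."""
        u = np.asarray(u, dtype=float)
        u = u / np.linalg.norm(u)
        c = self.cfg.cv(self.regions[self.region_index[t]], bcl) / 1000.0
        return c * math.sqrt(float(u @ self.G(t) @ u))

    def triangle_cv(self, t: int, bcl: float) -> float:
        """Base (cross-fiber) conduction speed of triangle t in mm/ms."""
        return self.cfg.cv(self.regions[self.region_index[t]], bcl) / 1000.0


def build_tensor_field(mesh: TriangularSurfaceMesh, cfg: SubstrateConfig) -> ConductionTensorField:
    """Assemble per-triangle tensors from fiber directions and region k."""
    cfg.validate_mesh(mesh)
    regions = sorted({str(r) for r in mesh.region})
    code = {r: i for i, r in enumerate(regions)}
    region_index = np.array([code[str(r)] for r in mesh.region], dtype=np.int64)
    k = np.array([cfg.k(r) for r in regions])[region_index]
    if (k < 1.0).any():
        raise ValueError("anisotropy ratio k must be >= 1")

    M = mesh.n_triangles
    ginv = np.zeros((M, 6))
    ginv[:, 0] = ginv[:, 3] = ginv[:, 5] = 1.0  # identity by default
    aniso = k > 1.0
    if aniso.any():
        if mesh.fiber is None:
            raise ValueError("anisotropic regions (k > 1) require fiber directions")
        f = mesh.fiber[aniso]
        w = (1.0 / k[aniso] - 1.0)[:, None]
        # G^-1 = I + (1/k - 1) f f'
        ginv[aniso, 0] = 1.0 + (w[:, 0] * f[:, 0] * f[:, 0])
        ginv[aniso, 1] = w[:, 0] * f[:, 0] * f[:, 1]
        ginv[aniso, 2] = w[:, 0] * f[:, 0] * f[:, 2]
        ginv[aniso, 3] = 1.0 + (w[:, 0] * f[:, 1] * f[:, 1])
        ginv[aniso, 4] = w[:, 0] * f[:, 1] * f[:, 2]
        ginv[aniso, 5] = 1.0 + (w[:, 0] * f[:, 2] * f[:, 2])
    return ConductionTensorField(
        mesh=mesh, cfg=cfg, ginv=ginv, k=k, region_index=region_index, regions=regions
    )


@dataclass
class ActivationField:
    """Result of a static activation solve.

    ``times`` in ms (+inf for unreached nodes); ``pred`` holds the activating
    node per node (-1 for stimuli/unreached); ``front`` labels the stimulus
    origin each node was reached from.
    """

    mesh: TriangularSurfaceMesh
    times: np.ndarray
    pred: np.ndarray
    front: np.ndarray
    stimulus_nodes: frozenset[int]
    adjacency: Adjacency = field(repr=False, default=None)

    @property
    def unreached(self) -> np.ndarray:
        return np.flatnonzero(~np.isfinite(self.times))

    def activation_vectors(self) -> np.ndarray:
        """Per-node vector from activating node to the node itself (mm).

        Zero for stimulus and unreached nodes.
        """
        vec = np.zeros_like(self.mesh.nodes)
        has = self.pred >= 0
        vec[has] = self.mesh.nodes[has] - self.mesh.nodes[self.pred[has]]
        return vec


def _quad(g, dx, dy, dz):
    return (
        g[0] * dx * dx
        + g[3] * dy * dy
        + g[5] * dz * dz
        + 2.0 * (g[1] * dx * dy + g[2] * dx * dz + g[4] * dy * dz)
    )


def exact_seed(
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    adjacency: Adjacency,
    node: int,
    radius_factor: float = 6.0,
) -> list[tuple[int, float]] | None:
    """Exact-metric seed times around a point source, or None.

    The discretized two-point update accumulates its largest error where the
    front is strongly curved, i.e. within the first few rings of a point
    stimulus; that error then propagates outward along characteristics.
    Within a ball that is homogeneous (single region/tensor, fully
    conductive) the eikonal solution is exactly the metric distance, so
    nodes there are seeded analytically.  Returns (node, metric_distance)
    pairs (time = onset + distance * inv_speed), or None when the
    neighborhood is heterogeneous.
    """
    inc = adjacency.node_triangles[node]
    if len(inc) == 0:
        return None
    edge_ids = [adjacency.edge_id(node, int(j)) for j in adjacency.node_neighbors[node]]
    if not edge_ids:
        return None
    radius = radius_factor * float(np.mean(adjacency.edge_lengths[edge_ids]))

    ref = int(inc[0])
    g = tensor_field.ginv[ref]
    ri = tensor_field.region_index[ref]
    pos = mesh.nodes
    origin = pos[node]

    ball = {int(node)}
    frontier = [int(node)]
    while frontier:
        nxt = []
        for i in frontier:
            for j in adjacency.node_neighbors[i]:
                j = int(j)
                if j not in ball and np.linalg.norm(pos[j] - origin) <= radius:
                    ball.add(j)
                    nxt.append(j)
        frontier = nxt
    tris = {int(t) for i in ball for t in adjacency.node_triangles[i]}
    for t in tris:
        if (
            not mesh.conductive[t]
            or tensor_field.region_index[t] != ri
            or not np.allclose(tensor_field.ginv[t], g, atol=1e-12)
        ):
            return None
    dist = {}
    for i in ball:
        d = pos[i] - origin
        dist[i] = math.sqrt(_quad(g, d[0], d[1], d[2]))
    # predecessors must stay edge-adjacent so back-tracing yields mesh paths:
    # each seeded node points to its metric-closest in-ball neighbor
    out = []
    for i in sorted(ball):
        if i == node:
            continue
        cands = [int(j) for j in adjacency.node_neighbors[i] if int(j) in ball and dist[int(j)] < dist[i]]
        if not cands:
            continue
        pred = min(cands, key=lambda j: dist[j])
        out.append((i, dist[i], pred))
    return out


def solve_activation(
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    stimuli: list[tuple[list[int] | np.ndarray, float]],
    bcl: float | np.ndarray | None = None,
    adjacency: Adjacency | None = None,
    seed_radius_factor: float = 6.0,
) -> ActivationField:
    """Static multifront fast-marching activation solve.

    Parameters
    ----------
    stimuli : list of (node_ids, onset_ms)
        Each entry seeds one front; ``front`` labels record which entry
        reached each node first.
    bcl : float or per-node array, optional
        Cycle length used to evaluate CV restitution per activated node.
        Defaults to the top of the substrate's validity range.

    Unreached nodes keep time +inf and are reported, not fatal.
    """
    cfg = tensor_field.cfg
    N = mesh.n_nodes
    if bcl is None:
        bcl = cfg.bcl_range[1]
    bcl_arr = np.broadcast_to(np.asarray(bcl, dtype=float), (N,))

    if adjacency is None:
        adjacency = build_adjacency(mesh)

    # inverse speed (ms/mm) per region per node, restitution-evaluated
    regions = tensor_field.regions
    inv_speed = np.empty((len(regions), N))
    for ri, label in enumerate(regions):
        cv = np.asarray(cfg.cv(label, bcl_arr), dtype=float)
        inv_speed[ri] = 1000.0 / cv

    pos = mesh.nodes
    tris = mesh.triangles
    cond = mesh.conductive
    ginv = tensor_field.ginv
    region_index = tensor_field.region_index

    inc_tris = [
        [int(t) for t in adjacency.node_triangles[i] if cond[t]] for i in range(N)
    ]

    stim_set: set[int] = set()
    heap: list[tuple[float, int, int, int]] = []
    any_conductive_stim = False
    for fid, (nodes_, onset) in enumerate(stimuli):
        nodes_ = np.atleast_1d(np.asarray(nodes_, dtype=np.int64))
        for n in nodes_:
            n = int(n)
            stim_set.add(n)
            if inc_tris[n]:
                any_conductive_stim = True
            heappush(heap, (float(onset), n, -1, fid))
        if len(nodes_) == 1 and seed_radius_factor > 0:
            s = int(nodes_[0])
            seeds = exact_seed(mesh, tensor_field, adjacency, s, seed_radius_factor)
            if seeds is not None:
                ri = tensor_field.region_index[int(adjacency.node_triangles[s][0])]
                for i, dist, pred_i in seeds:
                    heappush(heap, (float(onset) + dist * inv_speed[ri, i], i, pred_i, fid))
    if not heap:
        raise ValueError("at least one stimulus node is required")
    if not any_conductive_stim:
        raise ValueError("all stimulus nodes lie on non-conductive triangles")

    times = np.full(N, np.inf)
    pred = np.full(N, -1, dtype=np.int64)
    front = np.full(N, -1, dtype=np.int64)
    accepted = np.zeros(N, dtype=bool)

    P = pos.tolist()
    G6 = ginv.tolist()
    T3 = tris.tolist()

    while heap:
        t_i, i, p_i, fid = heappop(heap)
        if accepted[i]:
            continue
        accepted[i] = True
        times[i] = t_i
        pred[i] = p_i
        front[i] = fid
        Ai = P[i]
        for tri in inc_tris[i]:
            va, vb, vc = T3[tri]
            if va == i:
                o1, o2 = vb, vc
            elif vb == i:
                o1, o2 = va, vc
            else:
                o1, o2 = va, vb
            g = G6[tri]
            ri = region_index[tri]
            for j, o in ((o1, o2), (o2, o1)):
                if accepted[j]:
                    continue
                Cx, Cy, Cz = P[j]
                ic = inv_speed[ri, j]
                wx, wy, wz = Cx - Ai[0], Cy - Ai[1], Cz - Ai[2]
                q0 = _quad(g, wx, wy, wz)
                best = t_i + math.sqrt(q0) * ic
                pn = i
                if accepted[o]:
                    B = P[o]
                    tB = times[o]
                    ux, uy, uz = Cx - B[0], Cy - B[1], Cz - B[2]
                    cand_b = tB + math.sqrt(_quad(g, ux, uy, uz)) * ic
                    if cand_b < best:
                        best, pn = cand_b, o
                    ex, ey, ez = B[0] - Ai[0], B[1] - Ai[1], B[2] - Ai[2]
                    a = _quad(g, ex, ey, ez)
                    b = (
                        g[0] * ex * wx
                        + g[3] * ey * wy
                        + g[5] * ez * wz
                        + g[1] * (ex * wy + ey * wx)
                        + g[2] * (ex * wz + ez * wx)
                        + g[4] * (ey * wz + ez * wy)
                    )
                    dt = tB - t_i
                    m = dt / ic
                    D = a - m * m
                    if D > 1e-14:
                        inner = D * (a * q0 - b * b)
                        if inner >= 0.0:
                            root = abs(m) * math.sqrt(inner)
                            for lam in ((b * D + root) / (a * D), (b * D - root) / (a * D)):
                                if 0.0 < lam < 1.0 and (b - a * lam) * m >= 0.0:
                                    qq = q0 - 2.0 * b * lam + a * lam * lam
                                    if qq > 0.0:
                                        cand = t_i + lam * dt + math.sqrt(qq) * ic
                                        if cand < best:
                                            best = cand
                                            pn = i if lam <= 0.5 else o
                if best < times[j]:
                    times[j] = best  # tentative; finalized on acceptance
                    heappush(heap, (best, j, pn, fid))

    # reset tentative-but-never-accepted values
    times[~accepted] = np.inf
    return ActivationField(
        mesh=mesh,
        times=times,
        pred=pred,
        front=front,
        stimulus_nodes=frozenset(stim_set),
        adjacency=adjacency,
    )
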