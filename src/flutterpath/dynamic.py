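"""Event-driven dynamic propagation with CV and ERP restitution.

The engine reuses the static solver's local triangle updates but replaces the
single-pass acceptance rule with refractoriness bookkeeping: a node
re-activates at time t only if ``t - last_activation >= ERP(bcl)`` with
``bcl = t - last_activation``; an arrival into refractory tissue is a
conduction block and is dropped (the wavefront dies there, which reproduces
annihilation when the wavelength exceeds the circuit).  Propagation speeds
use ``CV(bcl)`` of the node being activated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np

from .eikonal import ConductionTensorField, _quad
from .mesh import Adjacency, TriangularSurfaceMesh, build_adjacency
from .restitution import SubstrateConfig

__all__ = ["DynamicState", "EventLog", "simulate_dynamic"]


@dataclass
class DynamicState:
    """Initial condition of a dynamic run.

    ``last_activation`` in ms (-inf for virgin nodes); ``front_nodes`` are
    treated as having just fired and seed propagation; ``init_bcl`` is the
    cycle length assumed for each node's previous beat.
    """

    last_activation: np.ndarray
    front_nodes: np.ndarray
    init_bcl: float | np.ndarray = 1000.0

    @classmethod
    def quiescent(cls, n_nodes: int, init_bcl: float = 1000.0) -> "DynamicState":
        return cls(
            last_activation=np.full(n_nodes, -np.inf),
            front_nodes=np.array([], dtype=np.int64),
            init_bcl=init_bcl,
        )


@dataclass
class EventLog:
    """Activation events plus a per-probe cycle summary."""

    events: list[tuple[int, float]]
    probe_node: int | None = None
    probe_times: np.ndarray = field(default_factory=lambda: np.array([]))
    quiescent_at: float | None = None

    @property
    def probe_intervals(self) -> np.ndarray:
        return np.diff(self.probe_times)

    @property
    def cycles_completed(self) -> int:
        return max(0, len(self.probe_times) - 1)


def _node_erp_regions(mesh: TriangularSurfaceMesh, adjacency: Adjacency) -> list[tuple[str, ...]]:
    """Distinct incident conductive-triangle regions per node (ERP uses the max)."""
    out = []
    for i in range(mesh.n_nodes):
        labels = sorted(
            {str(mesh.region[t]) for t in adjacency.node_triangles[i] if mesh.conductive[t]}
        )
        out.append(tuple(labels))
    return out


def simulate_dynamic(
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    cfg: SubstrateConfig,
    initial: DynamicState,
    duration: float,
    stimuli: list[tuple[list[int], float]] | None = None,
    probe: int | None = None,
    adjacency: Adjacency | None = None,
) -> EventLog:
    """Run the restitution-aware dynamic simulation for ``duration`` ms.

    The run ends at ``duration`` or at global quiescence (empty event queue).
    ``stimuli`` may inject additional (node_ids, onset) activations.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if adjacency is None:
        adjacency = build_adjacency(mesh)
    N = mesh.n_nodes
    bclmin, bclmax = cfg.bcl_range

    la = np.array(initial.last_activation, dtype=float).copy()
    init_bcl = np.broadcast_to(np.asarray(initial.init_bcl, dtype=float), (N,)).copy()

    regions = tensor_field.regions
    region_index = tensor_field.region_index
    cond = mesh.conductive
    erp_regions = _node_erp_regions(mesh, adjacency)
    erp_params = {r: cfg.properties(r).erp for r in regions}
    cv_params = {r: cfg.properties(r).cv for r in regions}

    def erp_of(i: int, bcl: float) -> float:
        b = min(max(bcl, bclmin), bclmax)
        return max(
            (erp_params[r].A - erp_params[r].B * math.exp(-b / erp_params[r].C))
            for r in erp_regions[i]
        )

    def inv_speed(region: str, bcl: float) -> float:
        b = min(max(bcl, bclmin), bclmax)
        p = cv_params[region]
        return 1000.0 / (p.A - p.B * math.exp(-b / p.C))

    inc_tris = [
        [int(t) for t in adjacency.node_triangles[i] if cond[t]] for i in range(N)
    ]
    P = mesh.nodes.tolist()
    G6 = tensor_field.ginv.tolist()
    T3 = mesh.triangles.tolist()

    # stale-neighbor window for two-point updates: activation fields are
    # 1-Lipschitz in the travel-time metric, so same-front co-contributors
    # lag by at most one edge travel time; allow a generous multiple.
    mean_edge = float(np.mean(adjacency.edge_lengths))
    slowest = max(inv_speed(r, bclmax) for r in regions)
    window = 6.0 * mean_edge * slowest * max(tensor_field.k.max(), 1.0)

    heap: list[tuple[float, int, float, int]] = []  # (t_cand, node, t_src, src)
    events: list[tuple[int, float]] = []
    probe_times: list[float] = []

    def push_from(i: int, t_i: float) -> None:
        """Emit candidate activations for neighbors of a node firing at t_i."""
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
            rlabel = regions[region_index[tri]]
            for j, o in ((o1, o2), (o2, o1)):
                la_j = la[j]
                if la_j >= t_i:
                    continue  # already ahead of this front
                Cx, Cy, Cz = P[j]
                Aix, Aiy, Aiz = Ai
                wx, wy, wz = Cx - Aix, Cy - Aiy, Cz - Aiz
                q0 = _quad(g, wx, wy, wz)
                # CV(bcl) of the node being activated: fixed-point, 2 sweeps
                bcl_j = (t_i - la_j) if math.isfinite(la_j) else init_bcl[j]
                ic = inv_speed(rlabel, bcl_j)
                for _ in range(2):
                    cand = t_i + math.sqrt(q0) * ic
                    bcl_j = (cand - la_j) if math.isfinite(la_j) else init_bcl[j]
                    ic = inv_speed(rlabel, bcl_j)
                best = t_i + math.sqrt(q0) * ic
                t_o = la[o]
                if math.isfinite(t_o) and t_o <= t_i and (t_i - t_o) < window:
                    B = P[o]
                    ex, ey, ez = B[0] - Aix, B[1] - Aiy, B[2] - Aiz
                    a = _quad(g, ex, ey, ez)
                    b = (
                        g[0] * ex * wx
                        + g[3] * ey * wy
                        + g[5] * ez * wz
                        + g[1] * (ex * wy + ey * wx)
                        + g[2] * (ex * wz + ez * wx)
                        + g[4] * (ey * wz + ez * wy)
                    )
                    dt = t_o - t_i
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
                heappush(heap, (best, j, t_i, i))

    for f in np.atleast_1d(np.asarray(initial.front_nodes, dtype=np.int64)):
        f = int(f)
        t_f = la[f]
        if not math.isfinite(t_f):
            la[f] = t_f = 0.0
        events.append((f, t_f))
        if probe is not None and f == probe:
            probe_times.append(t_f)
        push_from(f, t_f)

    for nodes_, onset in stimuli or ():
        nodes_ = np.atleast_1d(np.asarray(nodes_, dtype=np.int64))
        for n in nodes_:
            heappush(heap, (float(onset), int(n), -math.inf, -1))
        if len(nodes_) == 1:
            # same exact-metric point-source seeding as the static solver
            from .eikonal import exact_seed

            s = int(nodes_[0])
            seeds = exact_seed(mesh, tensor_field, adjacency, s)
            if seeds is not None and all(
                not math.isfinite(la[i]) for i, _, _ in seeds
            ):
                rlabel = regions[region_index[int(adjacency.node_triangles[s][0])]]
                for i, dist, _pred in seeds:
                    ic = inv_speed(rlabel, init_bcl[i])
                    heappush(heap, (float(onset) + dist * ic, i, -math.inf, -1))

    quiescent_at = None
    while heap:
        t_c, j, t_src, src = heappop(heap)
        if t_c > duration:
            break
        la_j = la[j]
        if la_j >= t_src and src >= 0:
            continue  # stale: j activated after this candidate was generated
        if math.isfinite(la_j):
            bcl = t_c - la_j
            if bcl <= 0 or bcl < erp_of(j, bcl):
                continue  # conduction block: arrival into refractory tissue
        la[j] = t_c
        events.append((j, t_c))
        if probe is not None and j == probe:
            probe_times.append(t_c)
        push_from(j, t_c)
    else:
        quiescent_at = events[-1][1] if events else 0.0

    return EventLog(
        events=events,
        probe_node=probe,
        probe_times=np.array(probe_times),
        quiescent_at=quiescent_at,
    )
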