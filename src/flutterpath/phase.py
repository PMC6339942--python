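"""Phase extrapolation from a reentrant loop and dynamic initialization.

A node's phase in [0, 2pi) encodes the time elapsed since its last
activation as a fraction of the reentry cycle: ``elapsed = phase/(2pi)*rtt``.
Loop nodes are anchored at ``2pi * s / rtt`` where s is the cumulative
anisotropic travel time along the loop; off-loop nodes are initialized along
an eikonal (travel-time) tree rooted on the loop and then relaxed by a
travel-time-offset-corrected circular-mean iteration to a fixed point.  All
phase arithmetic is circular; no branch cut is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .dynamic import DynamicState, EventLog, simulate_dynamic
from .eikonal import ConductionTensorField
from .loops import Loop, _edge_inv_speed
from .mesh import Adjacency, TriangularSurfaceMesh, build_adjacency
from .restitution import SubstrateConfig

__all__ = ["PhaseField", "extrapolate_phase", "phase_to_state", "assess_reentry"]

TWO_PI = 2.0 * math.pi


@dataclass
class PhaseField:
    """Converged (or best-effort) phase per node for one reentrant circuit."""

    mesh: TriangularSurfaceMesh
    phase: np.ndarray  # [0, 2pi) per node
    loop: Loop
    rtt: float
    converged: bool
    iterations: int
    max_updates: list[float]  # per-iteration max circular update, rad


def _loop_edge_times(loop, mesh, tensor_field, adjacency, bcl):
    return np.array(
        [
            np.linalg.norm(mesh.nodes[b] - mesh.nodes[a])
            * _edge_inv_speed(mesh, tensor_field, adjacency, a, b, bcl)
            for a, b in loop.edges()
        ]
    )


def extrapolate_phase(
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    loop: Loop,
    rtt: float | None = None,
    adjacency: Adjacency | None = None,
    tol: float = 1e-3,
    max_iter: int = 1000,
) -> PhaseField:
    """Extrapolate a loop's activation phase to the whole domain.

    Non-convergence within ``max_iter`` is flagged, not fatal.
    """
    if rtt is None:
        rtt = loop.rtt
    if rtt is None or rtt <= 0:
        raise ValueError("rtt must be positive (run compute_rtt first)")
    if adjacency is None:
        adjacency = build_adjacency(mesh)
    N = mesh.n_nodes

    # anchor phases: cumulative travel time along the loop, normalized
    edge_times = _loop_edge_times(loop, mesh, tensor_field, adjacency, rtt)
    cum = np.concatenate([[0.0], np.cumsum(edge_times[:-1])])
    loop_total = float(edge_times.sum())
    anchor = {n: TWO_PI * (c / max(loop_total, 1e-12)) % TWO_PI for n, c in zip(loop.nodes, cum)}

    # travel-time metric on traversable edges
    inv_times = np.empty(len(adjacency.edges))
    for eid, (a, b) in enumerate(adjacency.edges):
        if adjacency.traversable[eid]:
            inv_times[eid] = adjacency.edge_lengths[eid] * _edge_inv_speed(
                mesh, tensor_field, adjacency, int(a), int(b), rtt
            )
        else:
            inv_times[eid] = np.inf
    finite = np.isfinite(inv_times)
    graph = adjacency.traversable_csr(weights=np.where(finite, inv_times, 0.0))

    loop_nodes = np.array(sorted(set(loop.nodes)), dtype=np.int64)
    dist, predecessors, sources = dijkstra(
        graph,
        indices=loop_nodes,
        min_only=True,
        return_predecessors=True,
    )

    phase = np.zeros(N)
    reachable = np.isfinite(dist)
    for i in np.flatnonzero(reachable):
        src = int(sources[i])
        # wave spreads outward from the circuit: a node at travel-time d from
        # its nearest loop anchor activated d later, i.e. its elapsed time
        # (and phase) is smaller by d
        phase[i] = (anchor.get(src, 0.0) - TWO_PI * dist[i] / rtt) % TWO_PI
    for n, ph in anchor.items():
        phase[n] = ph

    fixed = np.zeros(N, dtype=bool)
    fixed[list(anchor)] = True

    # neighbor lists with per-edge time offsets, sign from the eikonal tree
    # (d smaller -> upstream -> prediction adds the edge's travel lag)
    nbrs: list[np.ndarray] = []
    offs: list[np.ndarray] = []
    for i in range(N):
        js, os_ = [], []
        for j in adjacency.node_neighbors[i]:
            eid = adjacency.edge_id(i, int(j))
            if not adjacency.traversable[eid] or not np.isfinite(inv_times[eid]):
                continue
            tau = TWO_PI * inv_times[eid] / rtt
            sign = -1.0 if dist[int(j)] < dist[i] else 1.0
            js.append(int(j))
            os_.append(sign * tau)
        nbrs.append(np.array(js, dtype=np.int64))
        offs.append(np.array(os_))

    free = np.flatnonzero(reachable & ~fixed)
    max_updates: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        worst = 0.0
        new_phase = phase.copy()
        for i in free:
            js = nbrs[i]
            if len(js) == 0:
                continue
            pred = phase[js] + offs[i]
            z = np.exp(1j * pred).sum()
            if abs(z) < 1e-12:
                continue
            val = float(np.angle(z)) % TWO_PI
            delta = abs(_circ_diff(val, phase[i]))
            if delta > worst:
                worst = delta
            new_phase[i] = val
        phase = new_phase
        max_updates.append(worst)
        if worst < tol:
            converged = True
            break

    return PhaseField(
        mesh=mesh,
        phase=phase % TWO_PI,
        loop=loop,
        rtt=float(rtt),
        converged=converged,
        iterations=it,
        max_updates=max_updates,
    )


def _circ_diff(a: float, b: float) -> float:
    d = (a - b + math.pi) % TWO_PI - math.pi
    return d


def phase_to_state(
    phase_field: PhaseField,
    cfg: SubstrateConfig,
    rtt: float | None = None,
    adjacency: Adjacency | None = None,
    front_width: float | None = None,
) -> DynamicState:
    """Convert a phase field into a dynamic initial state.

    Per node, elapsed time since last activation is ``phase/(2pi) * rtt``;
    nodes with elapsed below their ERP(rtt) start refractory, and the thin
    band at phase just above zero forms the active front.
    """
    rtt = phase_field.rtt if rtt is None else rtt
    if rtt is None or rtt <= 0:
        raise ValueError("rtt must be positive")
    mesh = phase_field.mesh
    if adjacency is None:
        adjacency = build_adjacency(mesh)

    elapsed = phase_field.phase / TWO_PI * rtt
    last_activation = -elapsed

    if front_width is None:
        # one mean-edge travel time at the slowest configured speed
        mean_edge = float(np.mean(adjacency.edge_lengths))
        slowest_cv = min(
            cfg.cv(r, rtt) for r in {str(x) for x in mesh.region}
        ) / 1000.0
        front_width = mean_edge / slowest_cv
    band = TWO_PI * front_width / rtt
    front_nodes = np.flatnonzero(phase_field.phase < band)

    return DynamicState(
        last_activation=last_activation,
        front_nodes=front_nodes,
        init_bcl=rtt,
    )


def assess_reentry(
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    cfg: SubstrateConfig,
    loop: Loop,
    duration_cycles: int = 100,
    adjacency: Adjacency | None = None,
    probe: int | None = None,
) -> dict:
    """Phase-extrapolate a vulnerable loop, run dynamics, grade stability.

    ``sustained`` requires the probe node to keep activating with intervals
    within [0.5, 2] x RTT for the whole run.
    """
    if not loop.wl_ok:
        raise ValueError("assess_reentry requires a loop passing the wavelength condition")
    if adjacency is None:
        adjacency = build_adjacency(mesh)
    pf = extrapolate_phase(mesh, tensor_field, loop, adjacency=adjacency)
    state = phase_to_state(pf, cfg, adjacency=adjacency)
    rtt = pf.rtt
    if probe is None:
        probe = int(loop.nodes[0])
    duration = duration_cycles * rtt * 1.05 + rtt
    logv: EventLog = simulate_dynamic(
        mesh, tensor_field, cfg, state, duration=duration, probe=probe, adjacency=adjacency
    )
    intervals = logv.probe_intervals
    cycles = int(len(intervals))
    ok = cycles >= duration_cycles and (
        len(intervals) == 0
        or bool(np.all((intervals >= 0.5 * rtt) & (intervals <= 2.0 * rtt)))
    )
    return {
        "sustained": bool(ok),
        "cycles_completed": cycles,
        "mean_cycle_length_ms": float(np.mean(intervals)) if cycles else float("nan"),
        "rtt_ms": float(rtt),
        "phase_converged": pf.converged,
        "phase_iterations": pf.iterations,
        "quiescent_at_ms": logv.quiescent_at,
    }
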