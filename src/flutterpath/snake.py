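"""Loop constriction by an on-surface geometric snake.

The snake's energy is the loop's anisotropic round-trip travel time, so
"constricting like a rubber band" and minimizing RTT coincide.  Each snaxel
moves under a smoothing pull toward the weighted mean of its neighbors along
the snake (linearly decreasing weights over N neighbors) plus a first-order
travel-time descent step; snaxels are re-projected to the surface and the
polyline is resampled to a target spacing every iteration.  An iteration is
only accepted if it does not increase the RTT, so the RTT trace is monotone
non-increasing.  The wavelength condition is re-checked each iteration and
the loop is discarded at its first failure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np
from scipy.spatial import cKDTree

from .eikonal import ConductionTensorField
from .loops import Loop, check_wavelength, compute_rtt
from .mesh import Adjacency, TriangularSurfaceMesh
from .restitution import SubstrateConfig

__all__ = [
    "SnakeOptions",
    "SnakeResult",
    "SurfaceLocator",
    "prune_common_segments",
    "constrict",
    "canonicalize_and_dedup",
]

log = logging.getLogger(__name__)


@dataclass
class SnakeOptions:
    n_neighbors: int = 30  # snaxel neighbors in the smoothing window
    tol: float = 0.1  # ms of RTT decrease below which an iteration counts as stalled
    patience: int = 5
    max_iter: int = 500
    spacing_factor: float = 1.5  # target snaxel spacing / mean mesh edge length
    step_factor: float = 0.5  # max move per iteration / spacing
    descent_weight: float = 0.3


@dataclass
class SnakeResult:
    status: str  # converged | unconverged | discarded_wl | degenerate
    iterations: int = 0
    rtt_trace: list[float] = field(default_factory=list)
    loop: Loop | None = None


def prune_common_segments(loop: Loop) -> Loop:
    """Drop the maximal shared stimulus-side run of the two half traces.

    An out-and-back loop (both halves identical) becomes an empty loop
    flagged degenerate.
    """
    if loop.half_i is None or loop.half_j is None:
        return loop
    hi, hj = loop.half_i, loop.half_j
    if hi[0] != hj[0]:
        return loop  # halves start on different stimulus nodes: nothing shared
    p = 0
    while p < len(hi) and p < len(hj) and hi[p] == hj[p]:
        p += 1
    if p == len(hi) or p == len(hj):
        return Loop(nodes=[], degenerate=True, provenance=loop.provenance)
    nodes = hi[p - 1 :] + list(reversed(hj[p:]))
    if len(nodes) < 3:
        return Loop(nodes=[], degenerate=True, provenance=loop.provenance)
    return Loop(
        nodes=nodes,
        provenance=loop.provenance,
        half_i=hi[p - 1 :],
        half_j=hj[p - 1 :],
    )


class SurfaceLocator:
    """Batch closest-point queries against a triangle mesh surface.

    With ``triangle_mask`` only the selected triangles (e.g. the conductive
    ones) are searched; returned triangle ids refer to the full mesh.
    """

    def __init__(
        self,
        mesh: TriangularSurfaceMesh,
        k_candidates: int = 8,
        triangle_mask: np.ndarray | None = None,
    ):
        self.mesh = mesh
        if triangle_mask is None:
            self._ids = np.arange(mesh.n_triangles)
        else:
            self._ids = np.flatnonzero(triangle_mask)
        if len(self._ids) == 0:
            raise ValueError("locator needs at least one triangle")
        self.k = min(k_candidates, len(self._ids))
        self._tree = cKDTree(mesh.triangle_centroids()[self._ids])
        t = mesh.triangles[self._ids]
        self._A = mesh.nodes[t[:, 0]]
        self._B = mesh.nodes[t[:, 1]]
        self._C = mesh.nodes[t[:, 2]]

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closest surface points and their triangle ids for an (n, 3) batch."""
        points = np.atleast_2d(points)
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        cand = _closest_on_triangles(
            points[:, None, :], self._A[idx], self._B[idx], self._C[idx]
        )
        d2 = np.sum((cand - points[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return cand[rows, best], self._ids[idx[rows, best]]


def _closest_on_triangles(P, A, B, C):
    """Vectorized closest point on triangles (Ericson's algorithm)."""
    ab = B - A
    ac = C - A
    ap = P - A
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = P - B
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = P - C
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom_ab = d1 - d3
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(denom_ab != 0, d1 / denom_ab, 0.0)
        w_ac = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    out = A + v_in[..., None] * ab + w_in[..., None] * ac  # interior default
    # edge BC region
    mask = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(mask[..., None], B + np.clip(w_bc, 0, 1)[..., None] * (C - B), out)
    # edge AC region
    mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(mask[..., None], A + np.clip(w_ac, 0, 1)[..., None] * ac, out)
    # edge AB region
    mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(mask[..., None], A + np.clip(v_ab, 0, 1)[..., None] * ab, out)
    # vertex regions
    mask = (d1 <= 0) & (d2 <= 0)
    out = np.where(mask[..., None], A, out)
    mask = (d3 >= 0) & (d4 <= 0)
    out = np.where(mask[..., None], B, out)
    mask = (d6 >= 0) & (d5 <= 0)
    out = np.where(mask[..., None], C, out)
    return out


def _resample_closed(points: np.ndarray, spacing: float, min_pts: int = 6) -> np.ndarray:
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = float(seg.sum())
    n = max(min_pts, int(round(total / spacing)))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def _segment_inv_speeds(tf, tri_ids, points, bcl):
    """Inverse speed (ms/mm) per closed-polyline segment, +inf off-conductive."""
    mesh = tf.mesh
    nxt = np.roll(np.arange(len(points)), -1)
    d = points[nxt] - points
    L = np.linalg.norm(d, axis=1)
    L = np.where(L < 1e-12, 1e-12, L)
    u = d / L[:, None]
    g = np.array([tf.G(int(t)) for t in tri_ids])
    ugu = np.einsum("ij,ijk,ik->i", u, g, u)
    cv = np.array(
        [tf.cfg.cv(tf.regions[tf.region_index[int(t)]], bcl) for t in tri_ids]
    ) / 1000.0
    inv = 1.0 / (cv * np.sqrt(np.maximum(ugu, 1e-12)))
    inv = np.where(mesh.conductive[tri_ids], inv, np.inf)
    return inv, L


def constrict(
    loop: Loop,
    mesh: TriangularSurfaceMesh,
    tensor_field: ConductionTensorField,
    cfg: SubstrateConfig,
    adjacency: Adjacency,
    options: SnakeOptions | None = None,
    locator: SurfaceLocator | None = None,
    cond_locator: SurfaceLocator | None = None,
) -> SnakeResult:
    """Constrict a loop candidate to a locally minimal-RTT cycle.

    Returns a :class:`SnakeResult`; ``status == "discarded_wl"`` means the
    wavelength condition failed mid-constriction (the loop contracts below
    the minimal sustainable circuit and is disregarded).
    """
    opts = options or SnakeOptions()
    if loop.degenerate or len(loop) < 3:
        return SnakeResult(status="degenerate")
    if locator is None:
        locator = SurfaceLocator(mesh)
    if cond_locator is None:
        # snaxels anchor to conductive triangles only; the unrestricted
        # locator is kept for lesion-crossing detection
        cond_locator = (
            locator
            if bool(mesh.conductive.all())
            else SurfaceLocator(mesh, triangle_mask=mesh.conductive)
        )

    mean_edge = float(np.mean(adjacency.edge_lengths))
    spacing = opts.spacing_factor * mean_edge
    max_step = opts.step_factor * spacing
    K = max(1, min(opts.n_neighbors // 2, 40))
    weights = np.arange(K, 0, -1.0)  # K, K-1, ..., 1

    pts = _resample_closed(mesh.nodes[loop.nodes], spacing)
    pts, tri_ids = cond_locator.project(pts)
    rtt_guess = cfg.bcl_range[1]
    inv, L = _segment_inv_speeds(tensor_field, tri_ids, pts, rtt_guess)
    rtt = float(np.dot(inv, L))
    if not math.isfinite(rtt):
        return SnakeResult(status="degenerate")
    trace = [rtt]
    stall = 0
    status = "unconverged"
    it = 0

    for it in range(1, opts.max_iter + 1):
        n = len(pts)
        if n < 4 or np.dot(inv, L).sum() <= 0:
            break
        Keff = min(K, n // 2 - 1) if n >= 6 else 1
        w = weights[:Keff]
        acc = np.zeros_like(pts)
        for d in range(1, Keff + 1):
            acc += w[d - 1] * (np.roll(pts, -d, axis=0) + np.roll(pts, d, axis=0))
        smooth_target = acc / (2.0 * w.sum())
        disp = smooth_target - pts

        # first-order descent of sum_i |p_i - p_{i-1}|/v + |p_{i+1} - p_i|/v
        nxt = np.roll(np.arange(n), -1)
        seg = pts[nxt] - pts
        seglen = np.linalg.norm(seg, axis=1)
        seglen = np.where(seglen < 1e-12, 1e-12, seglen)
        unit = seg / seglen[:, None]
        inv_f = np.where(np.isfinite(inv), inv, np.nanmax(np.where(np.isfinite(inv), inv, np.nan)))
        grad = -unit * inv_f[:, None] + np.roll(unit * inv_f[:, None], 1, axis=0)
        gn = np.linalg.norm(grad, axis=1)
        desc = np.where(
            gn[:, None] > 1e-12, -grad / np.maximum(gn, 1e-12)[:, None], 0.0
        )
        disp = disp + opts.descent_weight * spacing * desc

        norms = np.linalg.norm(disp, axis=1)
        scale = np.where(norms > max_step, max_step / np.maximum(norms, 1e-12), 1.0)
        cand = pts + disp * scale[:, None]
        cand, cand_tris = cond_locator.project(cand)
        # lesions are hard constraints: a segment whose midpoint is closest
        # to a non-conductive triangle is trying to cross one -> revert
        mid = 0.5 * (cand + np.roll(cand, -1, axis=0))
        _, mid_tris = locator.project(mid)
        bad_seg = ~mesh.conductive[mid_tris]
        if bad_seg.any():
            revert = bad_seg | np.roll(bad_seg, 1)
            cand[revert] = pts[revert]
            cand_tris[revert] = tri_ids[revert]

        new_pts = _resample_closed(cand, spacing)
        new_pts, new_tris = cond_locator.project(new_pts)
        new_inv, new_L = _segment_inv_speeds(tensor_field, new_tris, new_pts, rtt)
        new_rtt = float(np.dot(new_inv, new_L))

        if math.isfinite(new_rtt) and new_rtt <= rtt:
            improved = (rtt - new_rtt) >= opts.tol
            pts, tri_ids, inv, L = new_pts, new_tris, new_inv, new_L
            rtt = new_rtt
            stall = 0 if improved else stall + 1
        else:
            stall += 1
        trace.append(rtt)

        # wavelength condition re-checked every iteration; first failure discards
        labels = {tensor_field.regions[tensor_field.region_index[int(t)]] for t in tri_ids}
        worst_erp = max(cfg.erp(lbl, rtt) for lbl in labels)
        if worst_erp >= rtt:
            return SnakeResult(status="discarded_wl", iterations=it, rtt_trace=trace)
        if stall >= opts.patience:
            status = "converged"
            break

    snapped = _snap_to_vertices(pts, mesh, adjacency)
    if snapped is None or len(snapped) < 3:
        return SnakeResult(status="degenerate", iterations=it, rtt_trace=trace)
    out = Loop(nodes=snapped, provenance=dict(loop.provenance))
    try:
        compute_rtt(out, mesh, tensor_field, cfg, adjacency)
    except Exception:
        return SnakeResult(status="degenerate", iterations=it, rtt_trace=trace)
    check_wavelength(out, mesh, cfg, adjacency)
    if not out.wl_ok:
        return SnakeResult(status="discarded_wl", iterations=it, rtt_trace=trace)
    return SnakeResult(status=status, iterations=it, rtt_trace=trace, loop=out)


def _snap_to_vertices(pts: np.ndarray, mesh: TriangularSurfaceMesh, adjacency: Adjacency):
    """Snap snaxels to nearest mesh vertices and stitch into an edge cycle."""
    tree = cKDTree(mesh.nodes)
    _, verts = tree.query(pts)
    seq: list[int] = []
    for v in verts:
        if not seq or seq[-1] != int(v):
            seq.append(int(v))
    if len(seq) > 1 and seq[0] == seq[-1]:
        seq.pop()
    # stitch non-adjacent consecutive vertices with shortest traversable paths
    out: list[int] = []
    for a, b in zip(seq, seq[1:] + seq[:1]):
        out.append(a)
        if b not in adjacency.node_neighbors[a]:
            path = _short_path(adjacency, a, b)
            if path is None:
                return None
            out.extend(path[1:-1])
    # collapse immediate backtracks (x, y, x)
    cleaned: list[int] = []
    for v in out:
        if len(cleaned) >= 2 and cleaned[-2] == v:
            cleaned.pop()
        elif cleaned and cleaned[-1] == v:
            continue
        else:
            cleaned.append(v)
    if len(cleaned) >= 2 and cleaned[0] == cleaned[-1]:
        cleaned.pop()
    cleaned = _shorten_cycle(cleaned, mesh, adjacency)
    return cleaned if len(cleaned) >= 3 else None


def _shorten_cycle(
    nodes: list[int],
    mesh: TriangularSurfaceMesh,
    adjacency: Adjacency,
    window: int = 6,
    max_sweeps: int = 30,
) -> list[int]:
    """Locally shorten a vertex cycle by windowed shortest-path replacement.

    Vertex snapping turns a geodesic that runs between lattice rows into a
    staircase; replacing each short subpath by the shortest traversable
    edge path restores a locally shortest on-mesh cycle.  Windows span a few
    edges only, so the replacement cannot change the homotopy class across
    lesion bands or holes wider than the window.
    """

    def length(seq: list[int]) -> float:
        return float(
            sum(
                np.linalg.norm(mesh.nodes[b] - mesh.nodes[a])
                for a, b in zip(seq[:-1], seq[1:])
            )
        )

    for _ in range(max_sweeps):
        changed = False
        for w in range(2, window + 1):
            n = len(nodes)
            if n <= w + 2:
                continue
            q = 0
            while q < n and len(nodes) > w + 2:
                n = len(nodes)
                sub = [nodes[(q + t) % n] for t in range(w + 1)]
                if len(set(sub)) != len(sub):
                    q += 1
                    continue
                best = _short_path(adjacency, sub[0], sub[-1], max_cost=length(sub))
                if best is not None and length(best) < length(sub) - 1e-9 and len(set(best) & set(nodes[:])) <= len(best):
                    keep = [nodes[(q + t) % n] for t in range(w + 1, n)]
                    candidate = best + keep
                    # drop accidental immediate duplicates
                    merged: list[int] = []
                    for v in candidate:
                        if not merged or merged[-1] != v:
                            merged.append(v)
                    if len(merged) >= 3 and merged[0] == merged[-1]:
                        merged.pop()
                    if len(set(merged)) == len(merged) and len(merged) >= 3:
                        nodes = merged
                        changed = True
                q += 1
        if not changed:
            break
    return nodes


def _short_path(adjacency: Adjacency, a: int, b: int, max_cost: float = np.inf):
    """Dijkstra over traversable edges from a to b (early exit at b)."""
    dist = {a: 0.0}
    prev: dict[int, int] = {}
    heap = [(0.0, a)]
    while heap:
        d, u = heappop(heap)
        if u == b:
            path = [b]
            while path[-1] != a:
                path.append(prev[path[-1]])
            return list(reversed(path))
        if d > dist.get(u, np.inf) or d > max_cost:
            continue
        for v in adjacency.node_neighbors[u]:
            v = int(v)
            eid = adjacency.edge_id(u, v)
            if not adjacency.traversable[eid]:
                continue
            nd = d + adjacency.edge_lengths[eid]
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                prev[v] = u
                heappush(heap, (nd, v))
    return None


def canonicalize_and_dedup(loops: list[Loop]) -> list[Loop]:
    """Rotation/orientation-normalize loops and merge (near-)duplicates.

    Exact duplicates collapse to one; near-duplicates (node-set Jaccard >=
    0.9 and RTT within 2 ms) keep the lower-RTT representative.
    """
    canon: dict[tuple, Loop] = {}
    for lp in loops:
        if lp.degenerate or len(lp) < 3:
            continue
        key = _canonical_key(lp.nodes)
        old = canon.get(key)
        if old is None or (lp.rtt or np.inf) < (old.rtt or np.inf):
            canon[key] = Loop(
                nodes=list(key),
                rtt=lp.rtt,
                wl_ok=lp.wl_ok,
                provenance=dict(lp.provenance),
            )
    unique = list(canon.values())

    merged = 0
    kept: list[Loop] = []
    for lp in sorted(unique, key=lambda l: (l.rtt if l.rtt is not None else np.inf)):
        dup = False
        s = set(lp.nodes)
        for other in kept:
            o = set(other.nodes)
            jac = len(s & o) / len(s | o)
            if jac >= 0.9 and lp.rtt is not None and other.rtt is not None and abs(lp.rtt - other.rtt) < 2.0:
                dup = True
                merged += 1
                break
        if not dup:
            kept.append(lp)
    if merged:
        log.info("canonicalize_and_dedup merged %d near-duplicate loops", merged)
    kept.sort(key=lambda l: tuple(l.nodes))
    return kept


def _canonical_key(nodes: list[int]) -> tuple:
    """Lexicographically minimal rotation over both orientations."""
    best = None
    for seq in (list(nodes), list(reversed(nodes))):
        m = min(range(len(seq)), key=lambda q: seq[q])
        rot = tuple(seq[m:] + seq[:m])
        if best is None or rot < best:
            best = rot
    return best
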