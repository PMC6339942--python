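"""Stimulus orchestration and vulnerability-map aggregation.

For every stimulus site: solve activation, detect wavefront collisions,
assemble and prune loop candidates, filter by the wavelength condition,
constrict survivors with the geometric snake, and collect the vulnerable
loops.  Loops are globally canonicalized/deduplicated and rendered as
covered triangles.  The whole pipeline is deterministic (fixed iteration
orders, no randomness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .config import config_digest
from .eikonal import ConductionTensorField, build_tensor_field, solve_activation
from .loops import (
    Loop,
    assemble_loop,
    check_wavelength,
    cluster_collisions,
    compute_rtt,
    detect_collisions,
    seed_site,
)
from .mesh import Adjacency, TriangularSurfaceMesh, build_adjacency
from .restitution import SubstrateConfig
from .snake import SnakeOptions, SurfaceLocator, canonicalize_and_dedup, constrict, prune_common_segments

__all__ = ["VulnerabilityMap", "MapOptions", "select_stimulus_sites", "build_vulnerability_map", "coverage_sweep"]

log = logging.getLogger(__name__)


@dataclass
class MapOptions:
    snake: SnakeOptions = field(default_factory=SnakeOptions)
    max_clusters_per_stimulus: int = 200
    coverage_dilation: float = 0.0  # mm; 0 = strict vertex incidence


@dataclass
class VulnerabilityMap:
    loops: list[Loop]
    covered: np.ndarray  # bool per triangle
    coverage_fraction: float
    n_stimuli: int
    skipped_stimuli: int
    provenance: dict

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def summary(self) -> dict:
        return {
            "coverage_fraction": round(float(self.coverage_fraction), 6),
            "n_loops": self.n_loops,
            "n_stimuli": self.n_stimuli,
            "skips": self.skipped_stimuli,
            "digest": self.provenance.get("digest"),
        }


def select_stimulus_sites(
    mesh: TriangularSurfaceMesh,
    min_distance: float,
    adjacency: Adjacency | None = None,
) -> np.ndarray:
    """Greedy geodesic thinning of the node set, ascending node index.

    A node is kept iff no previously kept node lies within ``min_distance``
    (surface distance approximated on the edge graph).  ``min_distance = 0``
    keeps every node.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    n = mesh.n_nodes
    if adjacency is None:
        adjacency = build_adjacency(mesh)
    excitable = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(mesh.conductive):
        excitable[mesh.triangles[t]] = True
    if min_distance == 0:
        return np.flatnonzero(excitable).astype(np.int64)
    graph = adjacency.traversable_csr()
    kept: list[int] = []
    blocked = np.zeros(n, dtype=bool)
    for i in range(n):
        if blocked[i] or not excitable[i]:
            continue
        kept.append(i)
        dist = dijkstra(graph, indices=i, limit=min_distance, min_only=True)
        blocked |= np.isfinite(dist)
    return np.array(kept, dtype=np.int64)


def build_vulnerability_map(
    mesh: TriangularSurfaceMesh,
    cfg: SubstrateConfig,
    stimuli: np.ndarray | list[int],
    options: MapOptions | None = None,
    adjacency: Adjacency | None = None,
    tensor_field: ConductionTensorField | None = None,
) -> VulnerabilityMap:
    """Aggregate all constriction-surviving vulnerable loops over stimuli."""
    opts = options or MapOptions()
    if adjacency is None:
        adjacency = build_adjacency(mesh)
    if tensor_field is None:
        tensor_field = build_tensor_field(mesh, cfg)
    locator = SurfaceLocator(mesh)
    cond_locator = (
        locator
        if bool(mesh.conductive.all())
        else SurfaceLocator(mesh, triangle_mask=mesh.conductive)
    )

    collected: list[Loop] = []
    skipped = 0
    stimuli = np.asarray(stimuli, dtype=np.int64)
    for s in stimuli:
        try:
            collected.extend(
                _loops_for_stimulus(
                    int(s), mesh, cfg, tensor_field, adjacency, locator, cond_locator, opts
                )
            )
        except Exception as exc:  # per-stimulus failures are logged, not fatal
            log.warning("stimulus %d skipped: %s", int(s), exc)
            skipped += 1

    unique = canonicalize_and_dedup(collected)
    unique = [lp for lp in unique if lp.wl_ok]

    covered = _coverage(mesh, unique, opts.coverage_dilation)
    n_cond = int(mesh.conductive.sum())
    fraction = float(covered.sum()) / n_cond if n_cond else 0.0
    return VulnerabilityMap(
        loops=unique,
        covered=covered,
        coverage_fraction=fraction,
        n_stimuli=len(stimuli),
        skipped_stimuli=skipped,
        provenance={
            "stimuli": stimuli.tolist(),
            "digest": config_digest({"cfg": cfg, "stimuli": stimuli.tolist()}),
        },
    )


def _loops_for_stimulus(s, mesh, cfg, tensor_field, adjacency, locator, cond_locator, opts):
    af = solve_activation(mesh, tensor_field, [([s], 0.0)], adjacency=adjacency)
    sites = detect_collisions(af, adjacency)
    clusters = cluster_collisions(sites, adjacency)
    clusters.sort(key=lambda c: -max(x.collision_time for x in c))
    if len(clusters) > opts.max_clusters_per_stimulus:
        log.info(
            "stimulus %d: %d collision clusters capped to %d",
            s, len(clusters), opts.max_clusters_per_stimulus,
        )
        clusters = clusters[: opts.max_clusters_per_stimulus]

    out = []
    for cluster in clusters:
        site = seed_site(cluster)
        loop = prune_common_segments(assemble_loop(site, af))
        if loop.degenerate or len(loop) < 3:
            continue
        try:
            compute_rtt(loop, mesh, tensor_field, cfg, adjacency)
        except Exception:
            continue
        if not check_wavelength(loop, mesh, cfg, adjacency):
            continue
        result = constrict(
            loop, mesh, tensor_field, cfg, adjacency, opts.snake,
            locator=locator, cond_locator=cond_locator,
        )
        if result.loop is not None and result.loop.wl_ok:
            out.append(result.loop)
    return out


def _coverage(mesh: TriangularSurfaceMesh, loops: list[Loop], dilation: float) -> np.ndarray:
    """Triangle is covered iff a vertex lies on a loop (optionally dilated)."""
    covered = np.zeros(mesh.n_triangles, dtype=bool)
    if not loops:
        return covered
    on_loop = np.zeros(mesh.n_nodes, dtype=bool)
    for lp in loops:
        on_loop[list(lp.nodes)] = True
    hit = on_loop[mesh.triangles].any(axis=1)
    covered |= hit & mesh.conductive
    if dilation > 0:
        tree = cKDTree(mesh.nodes[on_loop])
        d, _ = tree.query(mesh.triangle_centroids())
        covered |= (d <= dilation) & mesh.conductive
    return covered


def coverage_sweep(
    mesh: TriangularSurfaceMesh,
    cfg: SubstrateConfig,
    parameter: str,
    values: list[float],
    base_min_distance: float = 0.0,
    options: MapOptions | None = None,
) -> list[dict]:
    """Coverage and loop count as one parameter varies.

    ``parameter`` is ``"cv_scale"`` (multiplies all CV curves) or
    ``"stimulus_min_distance"`` (thins the stimulus set).
    """
    if not values:
        raise ValueError("values must be non-empty")
    if parameter not in ("cv_scale", "stimulus_min_distance"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    adjacency = build_adjacency(mesh)
    rows = []
    for v in values:
        if parameter == "cv_scale":
            cfg_v = cfg.scaled_cv(float(v))
            stimuli = select_stimulus_sites(mesh, base_min_distance, adjacency)
        else:
            cfg_v = cfg
            stimuli = select_stimulus_sites(mesh, float(v), adjacency)
        vmap = build_vulnerability_map(
            mesh, cfg_v, stimuli, options=options, adjacency=adjacency
        )
        rows.append(
            {
                "value": float(v),
                "coverage_fraction": vmap.coverage_fraction,
                "n_loops": vmap.n_loops,
                "n_stimuli": int(len(stimuli)),
            }
        )
    return rows
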