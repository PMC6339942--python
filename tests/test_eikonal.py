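import math

import numpy as np
import pytest

from flutterpath import (
    build_adjacency,
    build_tensor_field,
    generate_planar_sheet,
    solve_activation,
    substrate_preset,
)
from flutterpath.config import substrate_from_dict
from helpers import oracle_times


def aniso_cfg(k, cv=600.0, erp=250.0):
    return substrate_from_dict(
        {"regions": {"default": {"cv": {"A": cv, "B": 0}, "erp": {"A": erp, "B": 0}, "k": k}}}
    )


class TestTensorField:
    def test_isotropic_identity(self, small_sheet, clinical_cfg):
        tf = build_tensor_field(small_sheet, clinical_cfg)
        for t in (0, 5, 11):
            np.testing.assert_allclose(tf.G(t), np.eye(3))
            np.testing.assert_allclose(tf.Ginv(t), np.eye(3))

    def test_eigenstructure_k4(self, small_sheet):
        tf = build_tensor_field(small_sheet, aniso_cfg(4.0))
        for t in (0, 7):
            G = tf.G(t)
            np.testing.assert_allclose(G, G.T)
            w, v = np.linalg.eigh(G)
            np.testing.assert_allclose(sorted(w), [1.0, 1.0, 4.0], atol=1e-12)
            principal = v[:, np.argmax(w)]
            fiber = small_sheet.fiber[t]
            assert abs(abs(principal @ fiber) - 1.0) < 1e-9

    def test_directional_speeds(self, small_sheet):
        tf = build_tensor_field(small_sheet, aniso_cfg(4.0, cv=600.0))
        c = 0.6  # mm/ms
        assert tf.directional_speed(0, [1, 0, 0], 1000.0) == pytest.approx(2 * c)
        assert tf.directional_speed(0, [0, 1, 0], 1000.0) == pytest.approx(c)

    def test_rotating_fiber_rotates_fast_axis(self, small_sheet):
        mesh = small_sheet.copy()
        phi = 0.7
        mesh.fiber = np.tile([math.cos(phi), math.sin(phi), 0.0], (mesh.n_triangles, 1))
        tf = build_tensor_field(mesh, aniso_cfg(4.0, cv=600.0))
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        assert tf.directional_speed(0, u, 1000.0) == pytest.approx(1.2)

    def test_missing_fiber_with_k_above_one(self, small_sheet):
        mesh = small_sheet.copy()
        mesh.fiber = None
        with pytest.raises(ValueError, match="fiber"):
            build_tensor_field(mesh, aniso_cfg(4.0))

    def test_k_below_one_rejected(self, small_sheet):
        with pytest.raises(ValueError):
            build_tensor_field(small_sheet, aniso_cfg(0.5))


class TestStaticSolve:
    def test_point_source_cone_solution(self):
        mesh = generate_planar_sheet(40.0, 40.0, 1.0)
        cfg = substrate_preset("clinical_example")  # 650 mm/s
        adj = build_adjacency(mesh)
        tf = build_tensor_field(mesh, cfg)
        stim = int(np.argmin(np.linalg.norm(mesh.nodes - [20, 20, 0], axis=1)))
        af = solve_activation(mesh, tf, [([stim], 0.0)], adjacency=adj)
        d = np.linalg.norm(mesh.nodes - mesh.nodes[stim], axis=1)
        mask = d > 2.0
        err = np.abs(af.times[mask] - d[mask] / 0.65) / (d[mask] / 0.65)
        assert err.max() < 0.02

    def test_error_decreases_under_refinement(self):
        maxerr = []
        for e in (2.0, 1.0):
            mesh = generate_planar_sheet(40.0, 40.0, e)
            cfg = substrate_preset("clinical_example")
            adj = build_adjacency(mesh)
            tf = build_tensor_field(mesh, cfg)
            stim = int(np.argmin(np.linalg.norm(mesh.nodes - [20, 20, 0], axis=1)))
            af = solve_activation(mesh, tf, [([stim], 0.0)], adjacency=adj)
            d = np.linalg.norm(mesh.nodes - mesh.nodes[stim], axis=1)
            mask = d > 10.0
            maxerr.append(np.abs(af.times[mask] - d[mask] / 0.65).max())
        assert maxerr[1] < maxerr[0]

    def test_anisotropic_elliptic_contours(self):
        mesh = generate_planar_sheet(60.0, 40.0, 1.0)
        adj = build_adjacency(mesh)
        tf = build_tensor_field(mesh, aniso_cfg(4.0, cv=500.0))
        stim = int(np.argmin(np.linalg.norm(mesh.nodes - [30, 20, 0], axis=1)))
        af = solve_activation(mesh, tf, [([stim], 0.0)], adjacency=adj)
        c = 0.5
        # along-fiber (x) speed 2c, cross-fiber (y) speed c -> 2:1 ellipse
        right = int(np.argmin(np.linalg.norm(mesh.nodes - (mesh.nodes[stim] + [16, 0, 0]), axis=1)))
        up = int(np.argmin(np.linalg.norm(mesh.nodes - (mesh.nodes[stim] + [0, 16, 0]), axis=1)))
        t_right = af.times[right]
        t_up = af.times[up]
        assert t_up / t_right == pytest.approx(2.0, rel=0.03)
        # oblique direction matches the exact anisotropic point-source time
        diag = int(np.argmin(np.linalg.norm(mesh.nodes - (mesh.nodes[stim] + [12, 12, 0]), axis=1)))
        dvec = mesh.nodes[diag] - mesh.nodes[stim]
        expected = math.sqrt(dvec @ np.diag([0.25, 1.0, 1.0]) @ dvec) / c
        assert af.times[diag] == pytest.approx(expected, rel=0.03)

    def test_two_front_meeting_at_midpoint(self):
        mesh = generate_planar_sheet(40.0, 10.0, 1.0)
        cfg = substrate_preset("clinical_example")
        adj = build_adjacency(mesh)
        tf = build_tensor_field(mesh, cfg)
        left = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 5, 0], axis=1)))
        right = int(np.argmin(np.linalg.norm(mesh.nodes - [40, 5, 0], axis=1)))
        af = solve_activation(mesh, tf, [([left], 0.0), ([right], 0.0)], adjacency=adj)
        x = mesh.nodes[:, 0]
        assert set(af.front[x < 15]) == {0}
        assert set(af.front[x > 25]) == {1}
        seam = np.abs(x[af.front == 0].max() - 20.0)
        assert seam < 2.0

    def test_oracle_agreement(self):
        mesh = generate_planar_sheet(30.0, 30.0, 1.0)
        cfg = substrate_preset("clinical_example")
        adj = build_adjacency(mesh)
        tf = build_tensor_field(mesh, cfg)
        stim = int(np.argmin(np.linalg.norm(mesh.nodes - [15, 15, 0], axis=1)))
        af = solve_activation(mesh, tf, [([stim], 0.0)], adjacency=adj)
        oracle = oracle_times(mesh, adj, stim, 0.65)
        d = np.linalg.norm(mesh.nodes - mesh.nodes[stim], axis=1)
        mask = d > 3.0
        rel = np.abs(af.times[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 0.02

    def test_speed_scaling_halves_times(self, small_sheet, small_sheet_adj):
        cfg = substrate_preset("clinical_example")
        tf1 = build_tensor_field(small_sheet, cfg)
        tf2 = build_tensor_field(small_sheet, cfg.scaled_cv(2.0))
        af1 = solve_activation(small_sheet, tf1, [([0], 0.0)], adjacency=small_sheet_adj)
        af2 = solve_activation(small_sheet, tf2, [([0], 0.0)], adjacency=small_sheet_adj)
        np.testing.assert_allclose(af2.times, af1.times / 2.0, rtol=1e-12)

    def test_isotropy_limit_k1_equals_fiberless(self, small_sheet, small_sheet_adj):
        cfg = aniso_cfg(1.0)
        tf_fiber = build_tensor_field(small_sheet, cfg)
        bare = small_sheet.copy()
        bare.fiber = None
        tf_bare = build_tensor_field(bare, cfg)
        af1 = solve_activation(small_sheet, tf_fiber, [([3], 0.0)], adjacency=small_sheet_adj)
        af2 = solve_activation(bare, tf_bare, [([3], 0.0)], adjacency=build_adjacency(bare))
        np.testing.assert_array_equal(af1.times, af2.times)

    def test_acceptance_order_is_causal(self, small_sheet, small_sheet_adj, clinical_cfg):
        # on an acute mesh, activation times sorted by acceptance = sorted times
        tf = build_tensor_field(small_sheet, clinical_cfg)
        af = solve_activation(small_sheet, tf, [([0], 0.0)], adjacency=small_sheet_adj)
        times = af.times[np.isfinite(af.times)]
        for i in np.flatnonzero(af.pred >= 0):
            assert af.times[af.pred[i]] < af.times[i]

    def test_nonconductive_region_unreached(self):
        mesh = generate_planar_sheet(20.0, 20.0, 1.0)
        c = mesh.triangle_centroids()
        mesh.conductive[c[:, 0] > 15.0] = False
        adj = build_adjacency(mesh)
        cfg = substrate_preset("clinical_example")
        tf = build_tensor_field(mesh, cfg)
        af = solve_activation(mesh, tf, [([0], 0.0)], adjacency=adj)
        deep = np.flatnonzero(mesh.nodes[:, 0] > 17.0)
        assert set(deep) <= set(af.unreached)

    def test_all_stimuli_nonconductive_is_fatal(self):
        mesh = generate_planar_sheet(20.0, 20.0, 1.0)
        c = mesh.triangle_centroids()
        mesh.conductive[c[:, 0] > 15.0] = False
        adj = build_adjacency(mesh)
        cfg = substrate_preset("clinical_example")
        tf = build_tensor_field(mesh, cfg)
        dead = int(np.argmax(mesh.nodes[:, 0]))
        with pytest.raises(ValueError, match="non-conductive"):
            solve_activation(mesh, tf, [([dead], 0.0)], adjacency=adj)

    def test_no_stimulus_is_fatal(self, small_sheet, small_sheet_adj, clinical_cfg):
        tf = build_tensor_field(small_sheet, clinical_cfg)
        with pytest.raises(ValueError):
            solve_activation(small_sheet, tf, [], adjacency=small_sheet_adj)

    def test_activation_vectors_match_predecessors(self, small_sheet, small_sheet_adj, clinical_cfg):
        tf = build_tensor_field(small_sheet, clinical_cfg)
        af = solve_activation(small_sheet, tf, [([0], 0.0)], adjacency=small_sheet_adj)
        vec = af.activation_vectors()
        for i in np.flatnonzero(af.pred >= 0):
            np.testing.assert_allclose(
                vec[i], small_sheet.nodes[i] - small_sheet.nodes[af.pred[i]]
            )
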