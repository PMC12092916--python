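"""His-Purkinje tree: topology, calibration, PMJs, proximal block."""

import dataclasses

import numpy as np
import pytest

from lotcrt import ConductionModel, TreeParams, solve_network
from lotcrt import purkinje as P
from lotcrt.errors import CalibrationError


def manual_tree(l_ant=20.0, l_post=40.0):
    """Hand-built five-fascicle tree with straight, known-length branches."""
    nodes = np.array([
        [0, 0, 0],        # 0 his root
        [0, 0, -10],      # 1 bifurcation
        [0, 0, -20],      # 2 left bundle end
        [l_ant, 0, -20],  # 3 anterior fascicle end (length l_ant)
        [0, l_post, -20],  # 4 posterior fascicle end (length l_post)
        [0, -40, -20],    # 5 septal fascicle end (length 40)
        [5, 0, -10],      # 6 right bundle end
        [5, 10, -10],     # 7 RV septal fascicle end (length 10)
        [5, -10, -10],    # 8 moderator band end (length 10)
    ])
    ea = np.array([0, 1, 2, 2, 2, 1, 6, 6])
    eb = np.array([1, 2, 3, 4, 5, 6, 7, 8])
    cls = np.array([P.HIS, P.LEFT_BUNDLE, P.FASCICLE, P.FASCICLE, P.FASCICLE,
                    P.RIGHT_BUNDLE, P.FASCICLE, P.FASCICLE])
    fas = np.array([P.NONE, P.NONE, P.LV_ANT, P.LV_POST, P.LV_SEPT,
                    P.NONE, P.RV_SEPT, P.RV_MOD_BAND])
    return P.PurkinjeTree(
        nodes=nodes.astype(float), edge_a=ea, edge_b=eb, edge_class=cls,
        edge_fascicle=fas, conductive=np.ones(len(ea), bool), his_root=0,
        fascicle_end_nodes={P.LV_ANT: 3, P.LV_POST: 4, P.LV_SEPT: 5,
                            P.RV_SEPT: 7, P.RV_MOD_BAND: 8},
        block_edge=1, hbp_node=2, lbbp_node=2)


def test_generated_tree_has_five_fascicles_and_is_connected(small_tree,
                                                            small_model):
    labels = set(small_tree.edge_fascicle) - {P.NONE}
    assert labels == {P.LV_ANT, P.LV_POST, P.LV_SEPT, P.RV_SEPT,
                      P.RV_MOD_BAND}
    t = solve_network(small_tree, small_model, [(small_tree.his_root, 0.0)])
    assert np.isfinite(t).all()
    # a tree on n nodes has exactly n - 1 edges
    assert small_tree.n_edges == small_tree.n_nodes - 1


def test_tree_determinism(small_mesh):
    t1 = P.generate_his_purkinje(small_mesh, TreeParams(seed=11))
    t2 = P.generate_his_purkinje(small_mesh, TreeParams(seed=11))
    assert np.array_equal(t1.nodes, t2.nodes)
    assert np.array_equal(t1.edge_a, t2.edge_a)
    assert np.array_equal(t1.pmj_mesh_nodes, t2.pmj_mesh_nodes)


def test_edge_lengths_match_node_distance(small_tree):
    d = np.linalg.norm(small_tree.nodes[small_tree.edge_a]
                       - small_tree.nodes[small_tree.edge_b], axis=1)
    assert np.allclose(small_tree.edge_length, d, atol=1e-6)


def test_lv_fascicle_nodes_on_lv_endocardium(small_mesh, small_tree):
    lv_edges = np.isin(small_tree.edge_fascicle, P.LV_FASCICLE_LABELS)
    lv_nodes = np.unique(np.concatenate([small_tree.edge_a[lv_edges],
                                         small_tree.edge_b[lv_edges]]))
    endo = small_mesh.vertices[small_mesh.surface_nodes("LV_ENDO")]
    from scipy.spatial import cKDTree
    d, _ = cKDTree(endo).query(small_tree.nodes[lv_nodes])
    assert d.max() < 1.0


def test_calibration_satisfies_sinus_timing(small_tree, small_model):
    t = solve_network(small_tree, small_model, [(small_tree.his_root, 0.0)])
    lv = [t[small_tree.fascicle_end_nodes[l]] for l in P.LV_FASCICLE_LABELS]
    rv = [t[small_tree.fascicle_end_nodes[l]] for l in P.RV_FASCICLE_LABELS]
    assert max(lv) - min(lv) <= 0.5
    assert min(rv) - max(lv) == pytest.approx(10.0, abs=0.5)


def test_calibration_idempotent(small_tree, small_model):
    again = P.calibrate_fascicle_cv(small_tree, small_model)
    for label, cv in small_model.fascicle_cv.items():
        assert abs(again.fascicle_cv[label] - cv) < 1e-9


def test_calibrated_cv_scales_with_path_length():
    """Closed form CV = L / (T - t_origin): doubling a non-anchor fascicle's
    path length doubles its calibrated CV."""
    m1 = P.calibrate_fascicle_cv(manual_tree(l_ant=20.0), ConductionModel())
    m2 = P.calibrate_fascicle_cv(manual_tree(l_ant=40.0), ConductionModel())
    assert m2.fascicle_cv[P.LV_ANT] == pytest.approx(
        2.0 * m1.fascicle_cv[P.LV_ANT])
    # the anchor fascicle (longest unconstrained arrival) keeps the trunk CV
    assert m1.fascicle_cv[P.LV_POST] == pytest.approx(3.0)


def test_calibration_offset_exact_on_manual_tree():
    tree = manual_tree()
    model = P.calibrate_fascicle_cv(tree, ConductionModel(), lv_rv_offset=10.0)
    t = solve_network(tree, model, [(0, 0.0)])
    lv = [t[tree.fascicle_end_nodes[l]] for l in P.LV_FASCICLE_LABELS]
    rv = [t[tree.fascicle_end_nodes[l]] for l in P.RV_FASCICLE_LABELS]
    assert max(lv) - min(lv) < 1e-9
    assert min(rv) - max(lv) == pytest.approx(10.0, abs=1e-9)


def test_unreachable_target_time_raises():
    # an RV fascicle whose unconstrained arrival is far beyond T + offset
    tree = manual_tree()
    tree.nodes[7] = [5.0, 300.0, -10.0]   # 300 mm RV septal branch
    with pytest.raises(CalibrationError):
        P.calibrate_fascicle_cv(tree, ConductionModel())


def test_pmj_density_scaling(small_mesh):
    t1 = P.generate_his_purkinje(small_mesh, TreeParams(seed=5,
                                                        pmj_density=1.5))
    t2 = P.generate_his_purkinje(small_mesh, TreeParams(seed=5,
                                                        pmj_density=3.0))
    ratio = len(t2.pmj_tree_nodes) / len(t1.pmj_tree_nodes)
    assert 1.6 <= ratio <= 2.4


def test_pmjs_cover_every_fascicle_and_sit_on_endocardium(small_mesh,
                                                          small_tree):
    endo = set(small_mesh.surface_nodes("LV_ENDO", "RV_ENDO_SEPTAL",
                                        "RV_ENDO_FREE"))
    assert all(int(n) in endo for n in small_tree.pmj_mesh_nodes)
    # each fascicle's subtree carries at least one PMJ
    parent = small_tree.parents()
    fas_of_edge = {}
    for a, b, f in zip(small_tree.edge_a, small_tree.edge_b,
                       small_tree.edge_fascicle):
        fas_of_edge[(int(a), int(b))] = int(f)
        fas_of_edge[(int(b), int(a))] = int(f)
    covered = set()
    for node in small_tree.pmj_tree_nodes:
        node = int(node)
        while parent[node] >= 0:
            covered.add(fas_of_edge[(node, int(parent[node]))])
            node = int(parent[node])
    assert set(P.LV_FASCICLE_LABELS + P.RV_FASCICLE_LABELS) <= covered


def test_proximal_block_isolates_lv_network(small_tree, small_model):
    blocked = P.apply_proximal_lbbb(small_tree)
    t = solve_network(blocked, small_model, [(blocked.his_root, 0.0)])
    t0 = solve_network(small_tree, small_model, [(small_tree.his_root, 0.0)])
    lv_edges = np.isin(small_tree.edge_fascicle, P.LV_FASCICLE_LABELS)
    lv_nodes = np.unique(np.concatenate([small_tree.edge_a[lv_edges],
                                         small_tree.edge_b[lv_edges]]))
    rv_edges = np.isin(small_tree.edge_fascicle, P.RV_FASCICLE_LABELS)
    rv_nodes = np.unique(np.concatenate([small_tree.edge_a[rv_edges],
                                         small_tree.edge_b[rv_edges]]))
    assert np.isinf(t[lv_nodes]).all()
    assert np.allclose(t[rv_nodes], t0[rv_nodes])
    # the distal left bundle remains a viable pacing target below the block
    t_lbbp = solve_network(blocked, small_model, [(blocked.lbbp_node, 0.0)])
    assert np.isfinite(t_lbbp[lv_nodes]).all()
    # the original tree is untouched (block applied on a copy)
    assert small_tree.conductive.all()


def test_tree_json_round_trip(tmp_path, small_tree):
    from lotcrt.io import read_tree_json, write_tree_json
    path = tmp_path / "tree.json"
    write_tree_json(small_tree, path)
    back = read_tree_json(path)
    assert np.array_equal(back.nodes, small_tree.nodes)
    assert np.array_equal(back.edge_fascicle, small_tree.edge_fascicle)
    assert np.array_equal(back.pmj_mesh_nodes, small_tree.pmj_mesh_nodes)
    assert back.lbbp_node == small_tree.lbbp_node
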