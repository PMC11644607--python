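"""Path-graph construction and shortest-path stem/leaf separation."""

import numpy as np
import pytest
from scipy.sparse.csgraph import bellman_ford

from phenopot3d import (LEAF, NOISE, STEM, GraphDisconnectedError, PointCloud,
                        RunConfig, SegmentationParams, backtrack_leaf_mask,
                        build_graph, coarse_segment, find_root, find_tips,
                        radius_noise_filter, shortest_path_tree, stem_from_mask)


def chain_graph(n, spacing=1.0):
    nodes = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * spacing])
    return build_graph(nodes, SegmentationParams(nbrs_threshold=1.5 * spacing))


def test_collinear_nodes_make_a_path():
    nodes = np.array([[0, 0, 0], [0, 0, 0.002], [0, 0, 0.004]])
    g = build_graph(nodes, SegmentationParams(nbrs_threshold=0.003))
    assert g.adjacency.nnz // 2 == 2
    assert not g.gap_edges


def test_single_node_graph():
    g = build_graph(np.array([[0.0, 0.0, 0.0]]), SegmentationParams())
    assert g.n_nodes == 1 and g.adjacency.nnz == 0
    shortest_path_tree(g, 0)
    assert g.reachable.all()


def test_gap_filling_bridges_closest_pair_once(rng):
    a = rng.normal(0, 0.0005, (40, 3))
    b = rng.normal(0, 0.0005, (40, 3)) + [0.01, 0, 0]
    nodes = np.vstack([a, b])
    g = build_graph(nodes, SegmentationParams(nbrs_threshold=0.003, k_nn=600))
    assert len(g.gap_edges) == 1
    i, j = g.gap_edges[0]
    # brute-force closest inter-cluster pair
    d = np.linalg.norm(a[:, None] - b[None], axis=-1)
    bi, bj = np.unravel_index(d.argmin(), d.shape)
    assert {i, j} == {bi, bj + 40}


def test_gap_filling_budget_too_small_raises():
    a = np.random.default_rng(0).normal(0, 0.0004, (60, 3))
    b = a + [0.05, 0, 0]
    with pytest.raises(GraphDisconnectedError) as err:
        build_graph(np.vstack([a, b]), SegmentationParams(nbrs_threshold=0.003, k_nn=3))
    assert sorted(err.value.component_sizes) == [60, 60]


def test_find_root_minimum_z_with_ties():
    nodes = np.array([[0, 0, 0.1], [0, 0, 0.0], [0, 0, 0.5]])
    assert find_root(build_graph(nodes, SegmentationParams(nbrs_threshold=1))) == 1
    tied = np.array([[1, 0, 0.0], [0, 0, 0.0], [0, 0, 1.0]])
    assert find_root(build_graph(tied, SegmentationParams(nbrs_threshold=2))) == 1


def test_find_root_matches_brute_force(rng):
    nodes = rng.normal(size=(200, 3))
    g = build_graph(nodes, SegmentationParams(nbrs_threshold=10))
    r = find_root(g)
    assert nodes[r, 2] == nodes[:, 2].min()


def test_chain_distances_and_tips():
    g = chain_graph(4)
    shortest_path_tree(g, 0)
    assert np.allclose(g.dist, [0, 1, 2, 3])
    assert list(find_tips(g)) == [3]


def test_y_graph_topology():
    # stem 0-1-2, branches 2-3-4 and 2-5-6
    nodes = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0.9, 0, 2.4],
                      [1.8, 0, 2.8], [-0.9, 0, 2.4], [-1.8, 0, 2.8]], float)
    g = build_graph(nodes, SegmentationParams(nbrs_threshold=1.1))
    shortest_path_tree(g, find_root(g))
    tips = set(find_tips(g))
    assert tips == {4, 6}
    # both tips' predecessor chains meet at the junction (node 2)
    for tip in tips:
        chain = [tip]
        while g.predecessor[chain[-1]] >= 0:
            chain.append(g.predecessor[chain[-1]])
        assert 2 in chain


def test_star_tip_count(rng):
    m = 6
    center = np.zeros((1, 3))
    angles = np.linspace(0, 2 * np.pi, m, endpoint=False)
    spokes = [np.array([np.cos(a), np.sin(a), 1.0]) * r
              for a in angles for r in (0.5, 1.0)]
    nodes = np.vstack([center] + spokes)
    g = build_graph(nodes, SegmentationParams(nbrs_threshold=1.2))
    shortest_path_tree(g, 0)
    assert len(find_tips(g)) == m


def test_dijkstra_matches_bellman_ford_oracle(rng):
    for _ in range(5):
        nodes = rng.uniform(0, 1, (150, 3))
        g = build_graph(nodes, SegmentationParams(nbrs_threshold=0.35, k_nn=600))
        shortest_path_tree(g, find_root(g))
        ref = bellman_ford(g.adjacency, directed=False, indices=g.root)
        assert np.allclose(g.dist, ref)


def test_backtrack_chain_marks_last_k_nodes():
    g = chain_graph(10)
    shortest_path_tree(g, 0)
    mask = backtrack_leaf_mask(g, find_tips(g), k_retrace=3)
    assert set(np.flatnonzero(mask)) == {7, 8, 9}


def test_backtrack_saturation_marks_all_but_root():
    g = chain_graph(10)
    shortest_path_tree(g, 0)
    mask = backtrack_leaf_mask(g, find_tips(g), k_retrace=50)
    assert set(np.flatnonzero(mask)) == set(range(1, 10))


def test_backtrack_k1_marks_exactly_tips():
    g = chain_graph(5)
    shortest_path_tree(g, 0)
    mask = backtrack_leaf_mask(g, find_tips(g), k_retrace=1)
    assert set(np.flatnonzero(mask)) == {4}


def test_backtrack_monotone_in_k(curved_plant):
    from phenopot3d.pipeline import preprocess_cloud
    from phenopot3d.preprocess import voxel_downsample
    cloud, truth, config = curved_plant
    clean, _ = preprocess_cloud(cloud, config)
    grid = voxel_downsample(clean, config.voxel_size)
    g = build_graph(grid, SegmentationParams.from_config(config))
    shortest_path_tree(g, find_root(g))
    tips = find_tips(g)
    prev = None
    for k in (5, 15, 30, 60, 120):
        mask = backtrack_leaf_mask(g, tips, k)
        if prev is not None:
            assert (mask | prev == mask).all(), "mask must grow with k_retrace"
        prev = mask


def test_stem_is_complement_of_leaf_mask():
    g = chain_graph(10)
    shortest_path_tree(g, 0)
    mask = np.zeros(10, dtype=bool)
    mask[[7, 8, 9]] = True
    labels = stem_from_mask(g, mask)
    assert set(np.flatnonzero(labels == STEM)) == set(range(7))
    assert set(np.flatnonzero(labels == LEAF)) == {7, 8, 9}
    all_leaf = stem_from_mask(g, np.ones(10, dtype=bool))
    assert (all_leaf[1:] == LEAF).all()
    none_leaf = stem_from_mask(g, np.zeros(10, dtype=bool))
    assert (none_leaf == STEM).all()


def test_radius_filter_matches_brute_force(rng):
    pts = np.vstack([rng.uniform(0, 0.05, (400, 3)), [[1.0, 1.0, 1.0]]])
    keep = radius_noise_filter(pts, radius=0.01, min_neighbors=3)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    counts = (d <= 0.01).sum(axis=1) - 1
    assert np.array_equal(keep, counts >= 3)
    assert not keep[-1]


def test_radius_filter_dense_blob_all_kept(rng):
    pts = rng.normal(0, 0.002, (200, 3))
    assert radius_noise_filter(pts, radius=0.01, min_neighbors=1).all()


def test_coarse_segment_rejects_tiny_cloud():
    with pytest.raises(ValueError, match="at least"):
        coarse_segment(PointCloud(np.random.default_rng(0).normal(size=(10, 3))),
                       RunConfig())


def test_coarse_segment_leaf_recall_on_synthetic(straight_result):
    result, truth = straight_result
    to = truth.organ[result.input_mask]
    pred = result.labeled.organ
    leaf_truth = to == LEAF
    recall = (pred[leaf_truth] == LEAF).mean()
    assert recall >= 0.9


def test_stem_only_plant_has_almost_no_leaf():
    from phenopot3d.pipeline import preprocess_cloud
    from phenopot3d.synthetic import generate_plant, stem_only_spec, suggested_config
    spec = stem_only_spec(17)
    cloud, truth = generate_plant(spec)
    config = suggested_config(spec).replace(k_retrace=1)
    clean, _ = preprocess_cloud(cloud, config)
    labeled = coarse_segment(clean, config)
    assert (labeled.organ == LEAF).mean() <= 0.01
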