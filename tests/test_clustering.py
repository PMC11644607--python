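"""Leaf instance clustering: k-means, DBSCAN, OBB overlap, fragment merging."""

import numpy as np
import pytest
from sklearn.cluster import DBSCAN as SkDBSCAN

from phenopot3d import (ClusterParams, LeafInstanceSet, dbscan_partition,
                        estimate_leaf_count, kmeans_partition, merge_fragments,
                        obb_overlap_ratio, points_obb, segment_leaves)
from phenopot3d.cloud import LEAF, STEM, LabeledCloud, PointCloud


def brute_force_dbscan(points, eps, min_pts):
    """Independent density-reachability oracle on the full distance matrix."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None], axis=-1)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for u in neighbors[j]:
                if labels[u] == -1:
                    labels[u] = cluster
                    if core[u]:
                        stack.append(u)
        cluster += 1
    return labels, core


def same_partition(a, b):
    """Equality up to relabeling (noise label -1 must match exactly)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def blobs(rng, centers, n=50, sigma=0.001):
    pts = np.vstack([rng.normal(0, sigma, (n, 3)) + c for c in centers])
    return pts


def test_leaf_count_equals_component_count(rng):
    centers = [[0, 0, 0], [0.05, 0, 0], [0, 0.05, 0]]
    pts = blobs(rng, centers)
    assert estimate_leaf_count(pts, linkage_radius=0.01) == 3
    assert estimate_leaf_count(blobs(rng, [[0, 0, 0]]), 0.01) == 1


def test_leaf_count_matches_union_find_oracle(rng):
    centers = rng.uniform(0, 1, (5, 3)) * 10  # far apart
    pts = blobs(rng, centers, n=30)
    # union-find oracle
    parent = list(range(len(pts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    for i, j in zip(*np.nonzero(d <= 0.02)):
        parent[find(i)] = find(j)
    expected = len({find(i) for i in range(len(pts))})
    assert estimate_leaf_count(pts, 0.02) == expected


def test_kmeans_recovers_separated_blobs(rng):
    pts = blobs(rng, [[0, 0, 0], [0.1, 0, 0]], n=60)
    labels = kmeans_partition(pts, 2, seed=0)
    assert len(np.unique(labels[:60])) == 1
    assert len(np.unique(labels[60:])) == 1
    assert labels[0] != labels[60]


def test_kmeans_edge_cases(rng):
    pts = rng.normal(size=(20, 3))
    assert (kmeans_partition(pts, 1, 0) == 0).all()
    assert len(np.unique(kmeans_partition(pts, 20, 0))) == 20
    with pytest.raises(ValueError):
        kmeans_partition(pts, 21, 0)


def test_kmeans_deterministic_given_seed(rng):
    pts = rng.normal(size=(200, 3))
    assert np.array_equal(kmeans_partition(pts, 4, seed=9),
                          kmeans_partition(pts, 4, seed=9))


def test_dbscan_two_blobs_no_noise(rng):
    pts = blobs(rng, [[0, 0, 0], [0.1, 0, 0]], n=50, sigma=0.001)
    labels = dbscan_partition(pts, eps=0.01, min_pts=5)
    assert set(labels) == {0, 1}
    oracle, _ = brute_force_dbscan(pts, 0.01, 5)
    assert same_partition(labels, oracle)


def test_dbscan_isolated_point_is_noise():
    pts = np.array([[0.0, 0.0, 0.0]])
    assert dbscan_partition(pts, eps=0.01, min_pts=2)[0] == -1


@pytest.mark.parametrize("seed", range(5))
def test_dbscan_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 0.1, (300, 3))
    eps, min_pts = 0.012, 4
    labels = dbscan_partition(pts, eps, min_pts)
    oracle, core = brute_force_dbscan(pts, eps, min_pts)
    # cluster membership of core points is unambiguous and must coincide
    assert same_partition(labels[core], oracle[core])
    assert np.array_equal(labels == -1, oracle == -1)
    # cross-check against the library implementation on core points
    sk = SkDBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    assert same_partition(labels[core], sk[core])


def test_obb_overlap_identical_and_disjoint(rng):
    pts = rng.uniform(0, 1, (100, 3))
    box = points_obb(pts)
    ratio, contact = obb_overlap_ratio(box, box)
    assert ratio == pytest.approx(1.0, abs=1e-6) and contact
    far = points_obb(pts + 100.0)
    ratio, contact = obb_overlap_ratio(box, far, gap_tolerance=0.01)
    assert ratio == 0.0 and not contact


def test_obb_overlap_axis_aligned_half_offset(rng):
    # unit cubes offset by 0.5 along x: intersection volume 0.5
    grid = np.array(np.meshgrid(*[np.linspace(0, 1, 6)] * 3)).reshape(3, -1).T
    a = points_obb(grid)
    b = points_obb(grid + [0.5, 0, 0])
    ratio, contact = obb_overlap_ratio(a, b)
    assert contact
    assert ratio == pytest.approx(0.5, abs=0.02)


def test_obb_overlap_monte_carlo_oriented(rng):
    # rotated boxes: compare against Monte-Carlo intersection volume
    from scipy.spatial.transform import Rotation
    pts = rng.uniform(-0.5, 0.5, (4000, 3)) * [1.0, 0.6, 0.3]
    rot = Rotation.from_euler("xyz", [20, 35, 50], degrees=True).as_matrix()
    a = points_obb(pts)
    b = points_obb(pts @ rot.T + [0.2, 0.1, 0.05])
    ratio, contact = obb_overlap_ratio(a, b)
    samples = rng.uniform(-0.7, 0.7, (200_000, 3))

    def inside(box, x):
        proj = np.abs((x - box.center) @ box.axes.T)
        return (proj <= box.half + 1e-12).all(axis=1)

    inter = (inside(a, samples) & inside(b, samples)).mean() * (1.4 ** 3)
    expected = inter / min(a.volume, b.volume)
    assert contact
    assert ratio == pytest.approx(expected, rel=0.05)


def test_merge_rejoins_split_halves(rng):
    # one blade sampled with a missing central strip: two touching fragments
    u = rng.uniform(-0.05, 0.05, 4000)
    v = rng.uniform(-0.02, 0.02, 4000)
    keep = np.abs(u) > 0.002
    pts = np.column_stack([u[keep], v[keep], np.zeros(keep.sum())])
    labels = (pts[:, 0] > 0).astype(np.int64)
    merged = merge_fragments(LeafInstanceSet(points=pts, labels=labels),
                             merge_overlap=0.3, gap_tolerance=0.005)
    assert merged.n_instances == 1


def test_merge_keeps_separate_leaves_apart(rng):
    a = np.column_stack([rng.uniform(0, 0.04, 500), rng.uniform(0, 0.02, 500),
                         np.zeros(500)])
    b = a + [0.09, 0, 0]  # 5 cm gap
    pts = np.vstack([a, b])
    labels = np.repeat([0, 1], 500)
    merged = merge_fragments(LeafInstanceSet(points=pts, labels=labels),
                             merge_overlap=0.3, gap_tolerance=0.005)
    assert merged.n_instances == 2


def test_merge_single_fragment_unchanged_and_idempotent(rng):
    pts = rng.normal(size=(200, 3))
    inst = LeafInstanceSet(points=pts, labels=np.zeros(200, dtype=np.int64))
    once = merge_fragments(inst)
    assert once.n_instances == 1
    twice = merge_fragments(once)
    assert np.array_equal(once.labels, twice.labels)


def test_segment_leaves_requires_leaf_points(rng):
    cloud = PointCloud(rng.normal(size=(50, 3)))
    labeled = LabeledCloud(cloud, np.full(50, STEM))
    with pytest.raises(ValueError, match="no leaf"):
        segment_leaves(labeled, ClusterParams())


def test_segment_leaves_single_leaf(rng):
    pts = np.column_stack([rng.uniform(0, 0.05, 2000), rng.uniform(0, 0.02, 2000),
                           rng.normal(0, 0.0003, 2000)])
    labeled = LabeledCloud(PointCloud(pts), np.full(2000, LEAF))
    inst = segment_leaves(labeled, ClusterParams(seed=0))
    assert inst.n_instances == 1
    assert (labeled.leaf_id >= 0).sum() == (inst.labels >= 0).sum()


def test_segment_leaves_recovers_instances_on_synthetic(curved_result):
    result, truth = curved_result
    from phenopot3d.evaluation import instance_jaccard
    tl = truth.leaf_id[result.input_mask]
    assert result.instances.n_instances == len(truth.leaf_traits)
    _, _, best = instance_jaccard(result.labeled.leaf_id, tl)
    assert all(j >= 0.9 for j in best.values())


def test_touching_leaves_fuse_with_low_confidence_flag():
    from phenopot3d.pipeline import run_pipeline
    from phenopot3d.synthetic import (generate_plant, suggested_config,
                                      touching_leaves_spec)
    spec = touching_leaves_spec(13)
    cloud, truth = generate_plant(spec)
    result = run_pipeline(cloud, suggested_config(spec))
    assert result.instances.n_instances <= len(truth.leaf_traits)
    if result.instances.n_instances < len(truth.leaf_traits):
        assert result.instances.low_confidence
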