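"""Coarse stem/leaf separation by shortest-path analysis on the voxel graph.

The plant surface, voxelized, becomes a geometric graph: voxel centers are
nodes, pairs closer than ``nbrs_threshold`` are edges weighted by Euclidean
distance.  Physically, paths from the lowest voxel (the stem base) to any
point of the plant run along the stem and then out into a leaf; the leaf
portion of such a path is its last stretch.  So: build a single-source
shortest-path tree from the root, find its tips (nodes that are nobody's
predecessor), walk each tip back ``k_retrace`` predecessor hops marking
visited nodes as leaf, and take the complement as stem.

Gaps in the sampled surface (petioles, occlusion) disconnect the radius
graph; they are bridged by the shortest available inter-component link
among each node's ``k_nn`` nearest neighbors, mirroring the gap-filling
step of the path analysis.

``k_retrace`` counts voxel hops: its metric reach is roughly
``k_retrace * hop length`` where hops are between ``voxel_size`` and
``nbrs_threshold`` long.  Values tuned at one voxel size must be rescaled
when the voxel size changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .cloud import LEAF, NOISE, STEM, LabeledCloud, PointCloud
from .config import RunConfig
from .preprocess import VoxelGrid, statistical_outlier_removal, voxel_downsample

_NO_PRED = -9999  # scipy's sentinel for "no predecessor"


class GraphDisconnectedError(RuntimeError):
    """Raised when gap filling cannot connect the voxel graph."""

    def __init__(self, component_sizes: list[int]):
        self.component_sizes = component_sizes
        super().__init__(
            "voxel graph still disconnected after gap filling; "
            f"component sizes: {sorted(component_sizes, reverse=True)}"
        )


@dataclass
class SegmentationParams:
    """Tunables of the path segmentation (see module docstring)."""

    k_nn: int = 600
    k_retrace: int = 135
    nbrs_threshold: float = 0.003
    noise_radius: float = 0.005
    noise_min_neighbors: int = 5
    max_orphan_fraction: float = 0.01  # tolerated unreachable voxels (labeled noise)

    def __post_init__(self) -> None:
        if self.k_nn < 1 or self.k_retrace < 1:
            raise ValueError("k_nn and k_retrace must be >= 1")
        if self.nbrs_threshold <= 0 or self.noise_radius <= 0:
            raise ValueError("distance thresholds must be positive")

    @classmethod
    def from_config(cls, config: RunConfig) -> "SegmentationParams":
        return cls(k_nn=config.k_nn, k_retrace=config.k_retrace,
                   nbrs_threshold=config.nbrs_threshold,
                   noise_radius=config.noise_radius,
                   noise_min_neighbors=config.noise_min_neighbors)


@dataclass
class PathGraph:
    """Weighted voxel-center graph with shortest-path-tree annotations."""

    nodes: np.ndarray                    # (n, 3) voxel centers
    adjacency: sparse.csr_matrix         # symmetric, weights = Euclidean distances
    gap_edges: list[tuple[int, int]] = field(default_factory=list)
    root: int | None = None
    predecessor: np.ndarray | None = None
    dist: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def reachable(self) -> np.ndarray:
        if self.dist is None:
            raise RuntimeError("run shortest_path_tree first")
        return np.isfinite(self.dist)


def _radius_edges(nodes: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    w = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
    return pairs, w


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def build_graph(grid: VoxelGrid | np.ndarray, params: SegmentationParams) -> PathGraph:
    """Radius graph over voxel centers, plus gap-filling bridges.

    Bridging adds, while more than one connected component remains, the
    shortest inter-component link found among each node's ``k_nn`` nearest
    neighbors (equivalent to Kruskal restricted to the k-NN candidate set).
    Components that cannot be bridged within the ``k_nn`` budget raise
    :class:`GraphDisconnectedError` when they exceed ``max_orphan_fraction``
    of the nodes; smaller orphans are left unreachable (labeled noise later).
    """
    nodes = grid.centers if isinstance(grid, VoxelGrid) else np.asarray(grid, float)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty voxel grid")
    pairs, weights = _radius_edges(nodes, params.nbrs_threshold)
    gap_edges: list[tuple[int, int]] = []
    if n > 1:
        uf = _UnionFind(n)
        for i, j in pairs:
            uf.union(int(i), int(j))
        n_comp = len({uf.find(i) for i in range(n)})
        k = 8
        tree = cKDTree(nodes)
        tried_full = False
        while n_comp > 1 and not tried_full:
            k = min(k, n - 1)
            tried_full = k >= min(params.k_nn, n - 1)
            k_query = min(k, params.k_nn)
            dist_k, idx_k = tree.query(nodes, k=k_query + 1)
            src = np.repeat(np.arange(n), k_query)
            dst = idx_k[:, 1:].ravel()
            length = dist_k[:, 1:].ravel()
            order = np.argsort(length, kind="stable")
            for e in order:
                i, j = int(src[e]), int(dst[e])
                if uf.union(i, j):
                    gap_edges.append((min(i, j), max(i, j)))
                    n_comp -= 1
                    if n_comp == 1:
                        break
            k *= 4
        if n_comp > 1:
            roots = np.array([uf.find(i) for i in range(n)])
            _, sizes = np.unique(roots, return_counts=True)
            orphans = sizes.sum() - sizes.max()
            if orphans > params.max_orphan_fraction * n:
                raise GraphDisconnectedError(sizes.tolist())
    if gap_edges:
        ge = np.array(gap_edges)
        gw = np.linalg.norm(nodes[ge[:, 0]] - nodes[ge[:, 1]], axis=1)
        pairs = np.vstack([pairs, ge]) if len(pairs) else ge
        weights = np.concatenate([weights, gw])
    if len(pairs):
        adj = sparse.coo_matrix(
            (np.concatenate([weights, weights]),
             (np.concatenate([pairs[:, 0], pairs[:, 1]]),
              np.concatenate([pairs[:, 1], pairs[:, 0]]))),
            shape=(n, n),
        ).tocsr()
    else:
        adj = sparse.csr_matrix((n, n))
    return PathGraph(nodes=nodes, adjacency=adj, gap_edges=gap_edges)


def find_root(graph: PathGraph) -> int:
    """Index of the lowest node (min z; ties broken by lowest x, then y)."""
    nodes = graph.nodes
    if len(nodes) == 0:
        raise ValueError("empty graph")
    order = np.lexsort((nodes[:, 1], nodes[:, 0], nodes[:, 2]))
    return int(order[0])


def shortest_path_tree(graph: PathGraph, root: int | None = None) -> PathGraph:
    """Fill the single-source shortest-path tree (Dijkstra) from the root."""
    if root is None:
        root = graph.root if graph.root is not None else find_root(graph)
    graph.root = int(root)
    dist, pred = dijkstra(graph.adjacency, directed=False, indices=graph.root,
                          return_predecessors=True)
    graph.dist = dist
    graph.predecessor = pred.astype(np.int64)
    return graph


def find_tips(graph: PathGraph) -> np.ndarray:
    """Reachable nodes that are no other node's predecessor (tree leaves)."""
    if graph.predecessor is None:
        raise RuntimeError("run shortest_path_tree first")
    is_pred = np.zeros(graph.n_nodes, dtype=bool)
    used = graph.predecessor[graph.predecessor != _NO_PRED]
    is_pred[used] = True
    tips = np.flatnonzero(graph.reachable & ~is_pred)
    return tips


def hop_scale(graph: PathGraph) -> float:
    """Median shortest-path-tree edge length: the metric size of one hop."""
    if graph.predecessor is None:
        raise RuntimeError("run shortest_path_tree first")
    has_pred = graph.predecessor != _NO_PRED
    if not has_pred.any():
        return 0.0
    edges = graph.nodes[has_pred] - graph.nodes[graph.predecessor[has_pred]]
    return float(np.median(np.linalg.norm(edges, axis=1)))


def backtrack_leaf_mask(graph: PathGraph, tips: np.ndarray, k_retrace: int) -> np.ndarray:
    """Leaf mask from bounded backtracking of the path tips.

    Each tip's influence is walked back toward the root for ``k_retrace``
    hops (one hop = the median tree edge length); a node is marked leaf
    only if *every* tip whose geodesic continues through it — every tip
    reachable from the node through nodes at greater root distance — lies
    within that range.  Equivalently, a node is leaf iff all paths beyond
    it dead-end within ``k_retrace`` hops.  Blades, whose geodesics
    terminate at the leaf boundary, saturate once the range covers their
    extent; stem nodes keep carrying paths to the rest of the plant and
    stay unmarked, up to the intrinsic apex band shorter than the range.
    The tip itself is hop 0, so ``k_retrace=1`` marks exactly the tips;
    the root is never marked.

    Implemented as a single descending sweep over the geodesic distance
    field with a union-find over superlevel components (a merge-tree
    traversal), which is deterministic and robust to the spurious lateral
    tips that shortest-path trees develop on densely sampled surfaces.
    """
    if graph.dist is None:
        raise RuntimeError("run shortest_path_tree first")
    if k_retrace < 1:
        raise ValueError("k_retrace must be >= 1")
    n = graph.n_nodes
    dist = graph.dist
    reachable = np.isfinite(dist)
    reach = k_retrace * hop_scale(graph)
    is_tip = np.zeros(n, dtype=bool)
    is_tip[np.asarray(tips, dtype=np.int64)] = True

    uf = _UnionFind(n)
    # farthest tip distance in each superlevel component; -inf until a tip joins
    comp_tip_max = np.where(is_tip, dist, -np.inf)
    processed = np.zeros(n, dtype=bool)
    mask = np.zeros(n, dtype=bool)
    indptr, indices = graph.adjacency.indptr, graph.adjacency.indices
    order = np.argsort(dist, kind="stable")[::-1]
    for v in order:
        if not reachable[v]:
            continue
        rv = uf.find(v)
        for u in indices[indptr[v]:indptr[v + 1]]:
            if processed[u]:
                ru = uf.find(u)
                if ru != rv:
                    m = max(comp_tip_max[ru], comp_tip_max[rv])
                    uf.parent[ru] = rv
                    comp_tip_max[rv] = m
        processed[v] = True
        # every superlevel component is born at a local max, which is a tip
        if comp_tip_max[rv] - dist[v] < reach:
            mask[v] = True
    if graph.root is not None:
        mask[graph.root] = False
    mask &= reachable
    return mask


def stem_from_mask(graph: PathGraph, leaf_mask: np.ndarray) -> np.ndarray:
    """Per-node organ labels: the mask inverse over reachable nodes is stem."""
    labels = np.full(graph.n_nodes, NOISE, dtype=np.int32)
    reachable = graph.reachable
    labels[reachable & ~leaf_mask] = STEM
    labels[reachable & leaf_mask] = LEAF
    return labels


def radius_noise_filter(points: np.ndarray, radius: float,
                        min_neighbors: int) -> np.ndarray:
    """Keep mask: point kept iff it has >= min_neighbors others within radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, float).reshape(-1, 3)
    tree = cKDTree(points)
    counts = np.array(tree.query_ball_point(points, radius, return_length=True))
    return (counts - 1) >= min_neighbors  # subtract self


MIN_CLOUD_SIZE = 50


def coarse_segment(cloud: PointCloud, config: RunConfig,
                   grid: VoxelGrid | None = None) -> LabeledCloud:
    """Full coarse stem/leaf segmentation of a preprocessed, metric cloud.

    Voxelize, build the path graph, run the shortest-path analysis, mark
    leaves by tip backtracking, invert for the stem, propagate voxel labels
    to points, then demote isolated stem points to noise.
    """
    if len(cloud) < MIN_CLOUD_SIZE:
        raise ValueError(
            f"cloud has {len(cloud)} points; at least {MIN_CLOUD_SIZE} required")
    params = SegmentationParams.from_config(config)
    if grid is None:
        grid = voxel_downsample(cloud, config.voxel_size)
    graph = build_graph(grid, params)
    shortest_path_tree(graph, find_root(graph))
    tips = find_tips(graph)
    leaf_mask = backtrack_leaf_mask(graph, tips, params.k_retrace)
    voxel_labels = stem_from_mask(graph, leaf_mask)
    labels = voxel_labels[grid.point_map]
    stem_idx = np.flatnonzero(labels == STEM)
    if len(stem_idx):
        keep = radius_noise_filter(cloud.points[stem_idx], params.noise_radius,
                                   params.noise_min_neighbors)
        labels[stem_idx[~keep]] = NOISE
    return LabeledCloud(cloud, labels)
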