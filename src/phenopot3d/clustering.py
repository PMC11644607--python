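"""Fine segmentation of the canopy into individual leaf instances.

The coarse stage delivers the leaf class as one undifferentiated canopy.
Instances are separated in three steps mirroring the fine-segmentation
stage: a k-means partition (k seeded by a connected-component leaf-count
estimate), DBSCAN inside each k-means cluster to split merged leaves and
shed sparse debris, and a final merge of fragments whose oriented
bounding boxes overlap or touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError, cKDTree
from sklearn.cluster import KMeans

from .cloud import LEAF, STEM, LabeledCloud
from .config import RunConfig


@dataclass
class ClusterParams:
    """Tunables of the instance segmentation."""

    eps: float | None = None          # None: 2.5 x median NN distance (data-adaptive)
    min_pts: int = 10
    kmeans_k: int | None = None       # None: connected-component estimate
    merge_overlap: float = 0.3
    merge_gap: float = 0.005
    min_instance_fraction: float = 0.02
    stem_contact_gap: float = 0.003   # canopy patches this close to the stem go back to it
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if not 0 < self.merge_overlap <= 1:
            raise ValueError("merge_overlap must lie in (0, 1]")

    @classmethod
    def from_config(cls, config: RunConfig) -> "ClusterParams":
        return cls(eps=config.eps, min_pts=config.min_pts, kmeans_k=config.kmeans_k,
                   merge_overlap=config.merge_overlap, merge_gap=config.merge_gap,
                   min_instance_fraction=config.min_instance_fraction,
                   stem_contact_gap=1.5 * config.voxel_size,
                   seed=config.seed)


@dataclass
class LeafInstanceSet:
    """Disjoint leaf instances over a fixed point array.

    ``labels[i]`` is the instance id of point ``i`` (dense ``0..m-1``) or
    ``-1`` for unassigned/noise points.
    """

    points: np.ndarray
    labels: np.ndarray
    low_confidence: bool = False      # set when leaves may be under-segmented
    boxes: list = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) and self.labels.max() >= 0 else 0

    def instance_indices(self, instance: int) -> np.ndarray:
        return np.flatnonzero(self.labels == instance)

    def instance_points(self, instance: int) -> np.ndarray:
        return self.points[self.labels == instance]


def median_nn_distance(points: np.ndarray) -> float:
    """Median nearest-neighbor distance: the sampling-density scale."""
    points = np.asarray(points, float).reshape(-1, 3)
    if len(points) < 2:
        return 0.0
    d, _ = cKDTree(points).query(points, k=2)
    return float(np.median(d[:, 1]))


def default_eps(points: np.ndarray) -> float:
    """Data-adaptive DBSCAN radius: 4 x the median nearest-neighbor distance.

    With the default density criterion (min_pts = 10) the radius must hold
    comfortably more than min_pts neighbors for interior blade points,
    otherwise the clustering sits at its percolation threshold and blades
    shatter; 4 x the sampling spacing yields ~25 expected neighbors on a
    surface while still separating blades a few millimeters apart.
    """
    return 4.0 * median_nn_distance(points)


def estimate_leaf_count(points: np.ndarray, linkage_radius: float,
                        min_component: int = 1) -> int:
    """Number of connected components of the radius graph at ``linkage_radius``.

    Components smaller than ``min_component`` points (stray debris shed by
    the coarse stage) are not counted.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("empty leaf set")
    pairs = cKDTree(points).query_pairs(linkage_radius, output_type="ndarray")
    n = len(points)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, member = connected_components(adj, directed=False)
    sizes = np.bincount(member, minlength=n_comp)
    return max(int((sizes >= min_component).sum()), 1)


def kmeans_partition(points: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means++ / Lloyd partition into k non-empty clusters."""
    points = np.asarray(points, float).reshape(-1, 3)
    if k > len(points):
        raise ValueError(f"k={k} exceeds point count {len(points)}")
    if k == len(points):
        return np.arange(len(points))
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                tol=1e-6, random_state=seed)
    return km.fit_predict(points)


def dbscan_partition(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Exact DBSCAN labels; -1 marks noise.

    A point is core iff it has >= ``min_pts`` neighbors within ``eps``
    (itself included).  Clusters are the connected components of core
    points under eps-reachability plus their border points; a border point
    claimable by several clusters goes to the cluster of its
    first-discovered core neighbor in index order, which makes the
    labeling deterministic.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    points = np.asarray(points, float).reshape(-1, 3)
    n = len(points)
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, eps)
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        queue = [i]
        while queue:
            j = queue.pop(0)
            for u in sorted(neighbors[j]):
                if labels[u] == -1:
                    labels[u] = cluster
                    if core[u]:
                        queue.append(u)
        cluster += 1
    return labels


# ---------------------------------------------------------------------------
# oriented bounding boxes and overlap
# ---------------------------------------------------------------------------

MIN_BOX_HALF_THICKNESS = 1e-4  # flat leaves inflated before volume math (m)


@dataclass(frozen=True)
class Box:
    """Oriented box: center, orthonormal axes (rows), half-extents."""

    center: np.ndarray
    axes: np.ndarray
    half: np.ndarray

    @property
    def volume(self) -> float:
        return float(8 * np.prod(self.half))

    def halfspaces(self, inflate: float = 0.0) -> np.ndarray:
        """Rows [a, b] of a.x <= b describing the (optionally grown) box."""
        rows = []
        for axis, h in zip(self.axes, self.half + inflate):
            for sign in (1.0, -1.0):
                a = sign * axis
                rows.append(np.append(a, -(a @ self.center + h)))
        return np.array(rows)


def points_obb(points: np.ndarray) -> Box:
    """PCA-oriented bounding box of a point set (half-extents = half-ranges)."""
    points = np.asarray(points, float).reshape(-1, 3)
    center = points.mean(axis=0)
    cov = np.cov((points - center).T) if len(points) > 1 else np.eye(3)
    eigval, eigvec = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order].T
    proj = (points - center) @ axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    box_center = center + ((lo + hi) / 2) @ axes
    half = np.maximum((hi - lo) / 2, MIN_BOX_HALF_THICKNESS)
    return Box(center=box_center, axes=axes, half=half)


def _intersection_volume(box_a: Box, box_b: Box, inflate: float = 0.0) -> float:
    """Exact intersection volume of two oriented boxes (0 when disjoint)."""
    halfspaces = np.vstack([box_a.halfspaces(inflate), box_b.halfspaces(inflate)])
    # Chebyshev center: maximize the slack radius r with a.x + r|a| <= b
    a, b = halfspaces[:, :3], -halfspaces[:, 3]
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    res = linprog(c=[0, 0, 0, -1], A_ub=np.hstack([a, norms]), b_ub=b,
                  bounds=[(None, None)] * 3 + [(0, None)], method="highs")
    if not res.success or res.x[3] <= 1e-12:
        return 0.0
    interior = res.x[:3]
    try:
        hs = HalfspaceIntersection(halfspaces, interior)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


def obb_overlap_ratio(box_a: Box, box_b: Box,
                      gap_tolerance: float = 0.0) -> tuple[float, bool]:
    """(intersection volume / smaller box volume, contact flag).

    The contact flag is true when the boxes intersect outright or their
    surfaces come within ``gap_tolerance`` of each other (tested on boxes
    grown by half the tolerance each).
    """
    inter = _intersection_volume(box_a, box_b)
    ratio = inter / min(box_a.volume, box_b.volume)
    contact = inter > 0
    if not contact and gap_tolerance > 0:
        contact = _intersection_volume(box_a, box_b, inflate=gap_tolerance / 2) > 0
    return float(min(ratio, 1.0)), bool(contact)


def merge_fragments(instances: LeafInstanceSet, merge_overlap: float = 0.3,
                    gap_tolerance: float = 0.005) -> LeafInstanceSet:
    """Iteratively merge fragments of one blade back into a single instance.

    A pair qualifies when its OBB overlap ratio reaches ``merge_overlap``,
    or when the fragments' boxes are in contact *and* their point sets come
    within ``gap_tolerance`` of each other (loose boxes of tilted blades
    often intersect even for clearly distinct leaves, so box contact alone
    is not trusted).  Boxes are recomputed after each merge and ids
    re-densified; the instance count never increases and the operation is
    idempotent once no pair qualifies.
    """
    labels = instances.labels.copy()
    points = instances.points
    ids = [int(i) for i in np.unique(labels) if i >= 0]
    boxes = {i: points_obb(points[labels == i]) for i in ids}
    merged = True
    while merged and len(ids) > 1:
        merged = False
        best: tuple[float, int, int] | None = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                ratio, contact = obb_overlap_ratio(boxes[i], boxes[j], gap_tolerance)
                if ratio >= merge_overlap or (
                        contact and _point_gap(points, labels, i, j) <= gap_tolerance):
                    if best is None or ratio > best[0]:
                        best = (ratio, i, j)
        if best is not None:
            _, i, j = best
            labels[labels == j] = i
            ids.remove(j)
            boxes.pop(j)
            boxes[i] = points_obb(points[labels == i])
            merged = True
    remap = {old: new for new, old in enumerate(sorted(ids))}
    out = np.full_like(labels, -1)
    for old, new in remap.items():
        out[labels == old] = new
    final_boxes = [boxes[old] for old in sorted(ids)]
    return LeafInstanceSet(points=points, labels=out,
                           low_confidence=instances.low_confidence,
                           boxes=final_boxes)


def _point_gap(points: np.ndarray, labels: np.ndarray, i: int, j: int) -> float:
    """Smallest point-to-point distance between two labeled fragments."""
    a = points[labels == i]
    b = points[labels == j]
    d, _ = cKDTree(b).query(a, k=1)
    return float(d.min())


def segment_leaves(labeled: LabeledCloud, params: ClusterParams) -> LeafInstanceSet:
    """Split the leaf class into instances and write leaf_id back.

    Pipeline: estimate the leaf count from radius-graph components,
    k-means partition with that k, DBSCAN within each k-means cluster
    (splitting merged leaves, shedding sparse debris), drop instances
    below ``min_instance_fraction`` of the canopy, reassign canopy
    patches that are surface-continuous with the stem (within
    ``stem_contact_gap``) back to the stem class — blades hang off the
    stem behind a petiole gap, so contiguous patches are backtracking
    overshoot, not leaves — then merge blade fragments by bounding-box
    contact/overlap.  Flags ``low_confidence`` when distinct instances
    sit closer than the DBSCAN radius or an instance separates at half
    that radius (adjacent leaves may be fused, as happens with tightly
    packed succulents).
    """
    leaf_idx = np.flatnonzero(labeled.organ == LEAF)
    if len(leaf_idx) == 0:
        raise ValueError("labeled cloud has no leaf points")
    points = labeled.points[leaf_idx]
    eps = params.eps if params.eps is not None else default_eps(points)
    min_size = max(int(params.min_instance_fraction * len(points)), params.min_pts)
    k = params.kmeans_k
    if k is None:
        k = estimate_leaf_count(points, linkage_radius=3 * eps, min_component=min_size)
    k = max(min(k, len(points)), 1)
    coarse = kmeans_partition(points, k, seed=params.seed)
    labels = np.full(len(points), -1, dtype=np.int64)
    next_id = 0
    for c in range(k):
        idx = np.flatnonzero(coarse == c)
        sub = dbscan_partition(points[idx], eps, params.min_pts)
        for s in np.unique(sub):
            if s < 0:
                continue
            labels[idx[sub == s]] = next_id
            next_id += 1
    # sparse-debris rejection: tiny instances are DBSCAN-noise at canopy scale
    keep_ids = [i for i in range(next_id) if (labels == i).sum() >= min_size]
    # stem-continuity reclamation of backtracking overshoot: a canopy patch
    # goes back to the stem when it is surface-continuous with it AND is
    # tube-like rather than sheet-like (a blade merely grazing the stem
    # keeps a flat OBB; the overshoot band is a shell around the stem)
    stem_points = labeled.organ_points(STEM)
    reclaimed: list[int] = []
    if len(stem_points) and params.stem_contact_gap > 0:
        stem_tree = cKDTree(stem_points)
        for i in keep_ids:
            pts_i = points[labels == i]
            d, _ = stem_tree.query(pts_i, k=1)
            if d.min() > params.stem_contact_gap:
                continue
            box = points_obb(pts_i)
            if box.half[2] >= 0.5 * box.half[1]:
                reclaimed.append(i)
    keep_ids = [i for i in keep_ids if i not in reclaimed]
    remap = {old: new for new, old in enumerate(keep_ids)}
    new_labels = np.array([remap.get(int(l), -1) for l in labels], dtype=np.int64)
    for i in reclaimed:
        labeled.organ[leaf_idx[labels == i]] = STEM
    instances = LeafInstanceSet(points=points, labels=new_labels)
    instances = merge_fragments(instances, params.merge_overlap, params.merge_gap)
    instances.low_confidence = _under_segmentation_risk(instances, eps)
    labeled.leaf_id[:] = -1
    labeled.leaf_id[leaf_idx] = instances.labels
    labeled.validate_leaf_ids()
    return instances


def _min_intercluster_gap(instances: LeafInstanceSet) -> float:
    """Smallest inter-instance point gap (inf for < 2 instances)."""
    m = instances.n_instances
    if m < 2:
        return np.inf
    gap = np.inf
    trees = [cKDTree(instances.instance_points(i)) for i in range(m)]
    for i in range(m):
        pts_i = instances.instance_points(i)
        for j in range(i + 1, m):
            d, _ = trees[j].query(pts_i, k=1)
            gap = min(gap, float(d.min()))
    return gap


def _under_segmentation_risk(instances: LeafInstanceSet, eps: float) -> bool:
    """True when leaves may be fused or about to fuse.

    Either two instances sit closer than eps (one density bridge away from
    merging), or a single instance falls apart at eps/2 — the signature of
    two near-parallel blades fused through a marginal density bridge.
    """
    if _min_intercluster_gap(instances) < eps:
        return True
    for i in range(instances.n_instances):
        pts = instances.instance_points(i)
        if len(pts) < 2:
            continue
        pairs = cKDTree(pts).query_pairs(eps / 2, output_type="ndarray")
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(len(pts), len(pts)))
        n_comp, member = connected_components(adj, directed=False)
        sizes = np.bincount(member, minlength=n_comp)
        if (sizes >= max(10, 0.05 * len(pts))).sum() > 1:
            return True
    return False
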