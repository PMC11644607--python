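"""Metric calibration and background filtering.

The upstream reconstruction delivers clouds in arbitrary model units; a
reference object of known physical size (a 0.03 m checkerboard square)
fixes the metric scale as K = h_real / h_model, applied to every
coordinate.  Background (pot, table) is removed with a z pass-through
filter, sensor outliers with a statistical k-NN distance criterion, and
the result is voxelized to feed the path graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import EmptyCloudError, PointCloud


@dataclass(frozen=True)
class CalibrationRef:
    """Known physical length and its model-unit measurement."""

    h_real: float
    h_model: float

    def __post_init__(self) -> None:
        if self.h_real <= 0 or self.h_model <= 0:
            raise ValueError("calibration lengths must be strictly positive")


@dataclass(frozen=True)
class ZBounds:
    """Open interval (z_min, z_max) of the pass-through filter, meters."""

    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError("z_min must be strictly below z_max")


@dataclass
class VoxelGrid:
    """Occupied-voxel decomposition of a cloud.

    ``point_map[i]`` gives the occupied-voxel index of input point ``i``
    (total: every point maps); ``centers`` are geometric voxel centers,
    ``centroids`` the mean of the member points (used for denoising).
    """

    voxel_size: float
    origin: np.ndarray
    centers: np.ndarray
    centroids: np.ndarray
    point_map: np.ndarray
    counts: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.centers)


def scale_factor(ref: CalibrationRef) -> float:
    """Metric correction factor K = h_real / h_model."""
    return ref.h_real / ref.h_model


def apply_scale(cloud: PointCloud, k: float) -> PointCloud:
    """Multiply every coordinate by K; pairwise distances scale by exactly K."""
    if k <= 0:
        raise ValueError("scale factor must be positive")
    return PointCloud(cloud.points * k, cloud.colors, source=cloud.source)


def pass_through_z(cloud: PointCloud, bounds: ZBounds) -> tuple[PointCloud, np.ndarray]:
    """Keep points with z strictly inside (z_min, z_max).

    Returns the kept sub-cloud (input order preserved) and the aligned
    boolean keep-mask.  An empty result is allowed but warned about.
    """
    z = cloud.points[:, 2]
    mask = (z > bounds.z_min) & (z < bounds.z_max)
    if not mask.any():
        warnings.warn("pass-through filter removed every point", stacklevel=2)
    return cloud.select(mask), mask


def statistical_outlier_removal(
    cloud: PointCloud, k_neighbors: int = 20, std_ratio: float = 2.0
) -> tuple[PointCloud, np.ndarray]:
    """Drop points whose mean k-NN distance exceeds mean(d) + std_ratio * std(d).

    Membership is permutation-invariant; the mask is aligned with input order.
    """
    n = len(cloud)
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} points, got {n}")
    tree = cKDTree(cloud.points)
    # k+1 because the query returns the point itself at distance 0
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    d = dists[:, 1:].mean(axis=1)
    if np.allclose(d, 0.0):
        warnings.warn("degenerate cloud (all points coincide); nothing removed",
                      stacklevel=2)
        return cloud.copy(), np.ones(n, dtype=bool)
    threshold = d.mean() + std_ratio * d.std()
    mask = d <= threshold
    return cloud.select(mask), mask


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> VoxelGrid:
    """Bucket points into a regular grid anchored at the per-axis minimum.

    Voxel index of point p is floor((p - origin) / voxel_size); the center
    of an occupied voxel is origin + (index + 0.5) * voxel_size.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if len(cloud) == 0:
        raise EmptyCloudError("cannot voxelize an empty cloud")
    pts = cloud.points
    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / voxel_size).astype(np.int64)
    # guard the max-coordinate point against floating roundoff pushing it out
    np.clip(idx, 0, None, out=idx)
    uniq, point_map, counts = np.unique(idx, axis=0, return_inverse=True,
                                        return_counts=True)
    centers = origin + (uniq + 0.5) * voxel_size
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, point_map, pts)
    centroids = sums / counts[:, None]
    return VoxelGrid(voxel_size=voxel_size, origin=origin, centers=centers,
                     centroids=centroids, point_map=point_map, counts=counts)


def voxel_denoise(cloud: PointCloud, voxel_size: float, min_count: int = 1) -> PointCloud:
    """Replace the cloud by per-voxel centroids.

    Averaging within a voxel suppresses isotropic sensor noise by roughly
    sqrt(points per voxel) while keeping the surface geometry; extent-type
    measurements (max pairwise distances) are taken on this thinned cloud.
    Voxels holding fewer than ``min_count`` points can be dropped: lone
    points in otherwise empty voxels are the un-averaged tail of the noise
    distribution, which caliper-type maxima are most sensitive to.
    """
    grid = voxel_downsample(cloud, voxel_size)
    keep = grid.counts >= min_count
    if not keep.any():
        keep = slice(None)
    return PointCloud(grid.centroids[keep], source=cloud.source)
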