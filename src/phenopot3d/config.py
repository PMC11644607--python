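"""Run configuration: every tunable of the pipeline in one YAML-mappable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the phenotyping pipeline.

    Defaults follow the reported effective operating point of the path
    segmentation (k_nn=600, k_retrace=135, nbrs_threshold=0.003 m).  Note
    that ``k_retrace`` counts voxel hops, so its metric reach scales with
    ``voxel_size``; small desk-scale plants need proportionally smaller
    values (see docs/methods.md).
    """

    # calibration / background removal
    scale_real: float = 0.03        # physical reference length (m); 0.03 m checker square
    scale_model: float = 0.03       # same length measured in model units
    z_min: float | None = None      # pass-through lower bound (m); None = keep all
    z_max: float | None = None
    sor_k_neighbors: int = 20       # statistical outlier removal: neighborhood size
    sor_std_ratio: float = 2.0      # ... and distance-threshold multiplier

    # voxelization / path segmentation
    voxel_size: float = 0.002       # m; must stay below nbrs_threshold for grid connectivity
    k_nn: int = 600                 # neighbor-candidate budget for gap-filling bridges
    k_retrace: int = 135            # backtracking steps from each path tip (voxel hops)
    nbrs_threshold: float = 0.003   # max valid neighbor distance (m)
    noise_radius: float = 0.005     # stem-class isolated-point removal radius (m)
    noise_min_neighbors: int = 5

    # leaf instance clustering
    eps: float | None = None        # DBSCAN radius (m); None = 2.5 x median NN distance
    min_pts: int = 10
    kmeans_k: int | None = None     # None = connected-component estimate
    merge_overlap: float = 0.3      # min OBB overlap ratio for fragment merging
    merge_gap: float = 0.005        # surface-gap tolerance for fragment contact (m)
    min_instance_fraction: float = 0.02  # instances smaller than this fraction of leaf points -> noise

    # trait extraction
    stem_offset: float = 0.05       # measurement height above pot surface (m)
    stem_slab: float = 0.006        # slab thickness around the measurement site (m)
    denoise_voxel: float = 0.003    # voxel-centroid grid for leaf measurements (m)
    stem_denoise_voxel: float = 0.004  # coarser grid for the stem caliper (m)
    max_edge: float | None = None   # triangulation edge cap (m); None = 4 x median NN spacing

    seed: int = 0

    def __post_init__(self) -> None:
        positive = ["scale_real", "scale_model", "sor_std_ratio", "voxel_size",
                    "nbrs_threshold", "noise_radius", "merge_overlap", "merge_gap",
                    "stem_slab", "denoise_voxel", "stem_denoise_voxel"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z_min is not None and self.z_max is not None and not self.z_min < self.z_max:
            raise ValueError("z_min must be below z_max")
        for name in ["sor_k_neighbors", "k_nn", "k_retrace", "min_pts"]:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.merge_overlap <= 1:
            raise ValueError("merge_overlap must lie in (0, 1]")
        if self.stem_offset < 0 or self.noise_min_neighbors < 0:
            raise ValueError("stem_offset and noise_min_neighbors must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update(kwargs)
        return RunConfig(**data)
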