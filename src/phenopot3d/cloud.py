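"""Point-cloud containers used throughout the pipeline.

Coordinates are metric (meters) once calibration has been applied; colors,
when present, are floats in [0, 1].  Per-point organ labels use small
integer codes (:data:`ORGAN_CODES`) so they can travel as PLY scalar
properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical organ label codes carried in PLY files
ORGAN_CODES = {"stem": 0, "leaf": 1, "noise": 2, "unassigned": 3}
ORGAN_NAMES = {v: k for k, v in ORGAN_CODES.items()}

STEM = ORGAN_CODES["stem"]
LEAF = ORGAN_CODES["leaf"]
NOISE = ORGAN_CODES["noise"]
UNASSIGNED = ORGAN_CODES["unassigned"]


class EmptyCloudError(ValueError):
    """Raised when an operation receives or produces a cloud with no points."""


@dataclass
class PointCloud:
    """An unordered set of 3D surface samples.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of x, y, z coordinates in meters.
    colors
        Optional ``(n, 3)`` float array of RGB values in ``[0, 1]``.
    source
        Free-text provenance string (file path, generator name, ...).
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError(
                    f"colors ({len(self.colors)}) and points ({len(self.points)}) differ in count"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def select(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Return a sub-cloud; preserves input order of the kept points."""
        return PointCloud(
            self.points[mask_or_index],
            None if self.colors is None else self.colors[mask_or_index],
            source=self.source,
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.colors is None else self.colors.copy(),
            self.source,
        )


@dataclass
class LabeledCloud:
    """A :class:`PointCloud` plus aligned per-point organ and leaf-instance labels.

    ``organ`` holds :data:`ORGAN_CODES` integers; ``leaf_id`` is ``>= 0``
    exactly for points labeled leaf and ``-1`` otherwise.
    """

    cloud: PointCloud
    organ: np.ndarray
    leaf_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.organ = np.asarray(self.organ, dtype=np.int32).reshape(-1)
        if self.leaf_id is None:
            self.leaf_id = np.full(len(self.cloud), -1, dtype=np.int32)
        self.leaf_id = np.asarray(self.leaf_id, dtype=np.int32).reshape(-1)
        n = len(self.cloud)
        if len(self.organ) != n or len(self.leaf_id) != n:
            raise ValueError("label arrays must align with points")
        if not np.isin(self.organ, list(ORGAN_CODES.values())).all():
            raise ValueError("unknown organ code")
        self.validate_leaf_ids()

    def validate_leaf_ids(self) -> None:
        is_leaf = self.organ == LEAF
        if (self.leaf_id[~is_leaf] >= 0).any():
            raise ValueError("leaf_id >= 0 on a non-leaf point")

    def __len__(self) -> int:
        return len(self.cloud)

    @property
    def points(self) -> np.ndarray:
        return self.cloud.points

    def organ_points(self, organ: int | str) -> np.ndarray:
        code = ORGAN_CODES[organ] if isinstance(organ, str) else organ
        return self.cloud.points[self.organ == code]

    def leaf_instance_points(self, leaf_id: int) -> np.ndarray:
        return self.cloud.points[self.leaf_id == leaf_id]
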