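"""End-to-end orchestration: preprocess -> coarse segment -> instances -> traits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cloud import LEAF, STEM, LabeledCloud, PointCloud
from .clustering import ClusterParams, LeafInstanceSet, segment_leaves
from .config import RunConfig
from .evaluation import SegmentationEval
from .pathseg import coarse_segment
from .preprocess import (CalibrationRef, ZBounds, apply_scale, pass_through_z,
                         scale_factor, statistical_outlier_removal)
from .traits import TraitReport, extract_traits


@dataclass
class PipelineResult:
    """Everything one plant yields, with masks tracing back to the input cloud."""

    cloud: PointCloud               # preprocessed, metric-scaled cloud
    input_mask: np.ndarray          # which input points survived preprocessing
    labeled: LabeledCloud
    instances: LeafInstanceSet | None
    traits: TraitReport
    segmentation: SegmentationEval


def preprocess_cloud(cloud: PointCloud, config: RunConfig) -> tuple[PointCloud, np.ndarray]:
    """Scale to meters, pass-through filter in z, remove statistical outliers.

    Returns the cleaned cloud and the boolean mask of surviving input points.
    """
    k = scale_factor(CalibrationRef(config.scale_real, config.scale_model))
    scaled = apply_scale(cloud, k)
    mask = np.ones(len(cloud), dtype=bool)
    if config.z_min is not None and config.z_max is not None:
        scaled, zmask = pass_through_z(scaled, ZBounds(config.z_min, config.z_max))
        mask[mask] = zmask
    if len(scaled) > config.sor_k_neighbors:
        scaled, smask = statistical_outlier_removal(
            scaled, config.sor_k_neighbors, config.sor_std_ratio)
        mask[mask.copy()] = smask
    return scaled, mask


def run_pipeline(cloud: PointCloud, config: RunConfig) -> PipelineResult:
    """Run the full phenotyping chain on one raw plant cloud."""
    clean, input_mask = preprocess_cloud(cloud, config)
    labeled = coarse_segment(clean, config)
    n_total = len(labeled)
    instances = None
    n_assigned = 0
    if (labeled.organ == LEAF).any():
        instances = segment_leaves(labeled, ClusterParams.from_config(config))
        n_assigned = int((instances.labels >= 0).sum())
    # count the leaf class after instance clustering: the fine stage may
    # hand stem-continuous canopy patches back to the stem
    n_leaf = int((labeled.organ == LEAF).sum())
    traits = extract_traits(labeled, instances, config)
    seg = SegmentationEval(n_total=n_total, n_leaf=n_leaf,
                           n_canopy_segmented=n_assigned)
    return PipelineResult(cloud=clean, input_mask=input_mask, labeled=labeled,
                          instances=instances, traits=traits, segmentation=seg)


def sweep_parameter(cloud: PointCloud, truth_organ: np.ndarray, config: RunConfig,
                    param: str, values) -> pd.DataFrame:
    """Coarse-segmentation precision/recall as one parameter varies.

    Runs the coarse stage on the (already preprocessed) ``cloud`` for each
    value of ``param`` (one of ``k_retrace``, ``k_nn``, ``nbrs_threshold``)
    and scores the stem/leaf labels against the aligned ground-truth organ
    array.  Configurations whose voxel graph cannot be connected are
    recorded with NaN scores and ``error`` set.
    """
    from .evaluation import segmentation_prf
    from .pathseg import GraphDisconnectedError

    if param not in ("k_retrace", "k_nn", "nbrs_threshold"):
        raise ValueError(f"unknown sweep parameter {param!r}")
    rows = []
    for value in values:
        cfg = config.replace(**{param: value})
        row = {param: value, "error": ""}
        try:
            labeled = coarse_segment(cloud, cfg)
            scores = segmentation_prf(labeled.organ, truth_organ,
                                      classes=[STEM, LEAF])
            row.update(
                stem_precision=scores[STEM].precision, stem_recall=scores[STEM].recall,
                stem_f1=scores[STEM].f1, leaf_precision=scores[LEAF].precision,
                leaf_recall=scores[LEAF].recall, leaf_f1=scores[LEAF].f1,
            )
        except GraphDisconnectedError as exc:
            row.update(stem_precision=np.nan, stem_recall=np.nan, stem_f1=np.nan,
                       leaf_precision=np.nan, leaf_recall=np.nan, leaf_f1=np.nan,
                       error=f"disconnected: {sorted(exc.component_sizes)[-3:]}")
        rows.append(row)
    return pd.DataFrame(rows)
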