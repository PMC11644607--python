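"""Evaluation statistics: segmentation rates, R², cloud-to-cloud distance, ICP.

The stem/leaf segmentation rate R_l = N_l / N x 100% relates the leaf
point count after stem/leaf separation to the cloud size before it; the
canopy rate R_S = N_S / N_l x 100% relates instance-assigned canopy
points to the leaf class.  Accuracy of recovered traits is scored with
R² = 1 - SSE/SST; cloud-to-cloud comparison uses per-point nearest
distances and their root mean square, after optional rigid ICP
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud


# ---------------------------------------------------------------------------
# segmentation rates
# ---------------------------------------------------------------------------

def stem_leaf_rate(n_leaf: float, n_total: float) -> float:
    """R_l = N_l / N x 100 (percent)."""
    if n_total <= 0:
        raise ZeroDivisionError("n_total must be positive")
    if not 0 <= n_leaf <= n_total:
        raise ValueError("need 0 <= n_leaf <= n_total")
    return 100.0 * n_leaf / n_total


def canopy_rate(n_canopy_segmented: float, n_leaf: float) -> float:
    """R_S = N_S / N_l x 100 (percent)."""
    if n_leaf <= 0:
        raise ZeroDivisionError("n_leaf must be positive")
    if not 0 <= n_canopy_segmented <= n_leaf:
        raise ValueError("need 0 <= n_canopy_segmented <= n_leaf")
    return 100.0 * n_canopy_segmented / n_leaf


def table_proportion(numerator: float, denominator: float, decimals: int = 3) -> float:
    """Proportion rounded half-up, as printed in segmentation summary tables."""
    value = Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SegmentationEval:
    """Point-count bookkeeping of a two-stage segmentation."""

    n_total: int
    n_leaf: int
    n_canopy_segmented: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_canopy_segmented <= self.n_leaf <= self.n_total:
            raise ValueError("counts must satisfy N_S <= N_l <= N")

    @property
    def r_l(self) -> float:
        return stem_leaf_rate(self.n_leaf, self.n_total)

    @property
    def r_s(self) -> float:
        return canopy_rate(self.n_canopy_segmented, self.n_leaf)


# ---------------------------------------------------------------------------
# regression accuracy
# ---------------------------------------------------------------------------

def r_squared(predicted, reference) -> float:
    """R² = 1 - SSE/SST of predictions against a non-constant reference."""
    predicted = np.asarray(predicted, float).ravel()
    reference = np.asarray(reference, float).ravel()
    if len(predicted) != len(reference) or len(reference) < 2:
        raise ValueError("need equal-length arrays of at least 2 values")
    sst = float(np.sum((reference - reference.mean()) ** 2))
    if sst == 0:
        raise ValueError("reference values are constant; R² undefined")
    sse = float(np.sum((reference - predicted) ** 2))
    return 1.0 - sse / sst


def fit_line_r2(measured, reference) -> tuple[float, float, float]:
    """Least-squares line measured ~ slope*reference + intercept, plus its R².

    This is how recovered-vs-true trait agreement is conventionally
    reported: fit the calibration line, then score the fitted values
    against the measurements with R² (equivalently the squared Pearson
    correlation).
    """
    measured = np.asarray(measured, float).ravel()
    reference = np.asarray(reference, float).ravel()
    slope, intercept = np.polyfit(reference, measured, 1)
    fitted = slope * reference + intercept
    return float(slope), float(intercept), r_squared(fitted, measured)


# ---------------------------------------------------------------------------
# cloud-to-cloud comparison
# ---------------------------------------------------------------------------

def nn_distances(compared: PointCloud | np.ndarray,
                 reference: PointCloud | np.ndarray) -> np.ndarray:
    """Distance from each compared point to its nearest reference point."""
    comp = compared.points if isinstance(compared, PointCloud) else np.asarray(compared, float)
    ref = reference.points if isinstance(reference, PointCloud) else np.asarray(reference, float)
    if len(comp) == 0 or len(ref) == 0:
        raise ValueError("both clouds must be non-empty")
    d, _ = cKDTree(ref).query(comp, k=1)
    return d


def rms_distance(distances) -> float:
    """R = sqrt(sum(D_i^2) / n)."""
    d = np.asarray(distances, float).ravel()
    if len(d) == 0:
        raise ValueError("empty distance list")
    return float(np.sqrt(np.mean(d ** 2)))


def mean_distance(distances) -> float:
    """Arithmetic mean of the D_i (companion reading of the average distance)."""
    d = np.asarray(distances, float).ravel()
    if len(d) == 0:
        raise ValueError("empty distance list")
    return float(d.mean())


@dataclass
class ICPResult:
    rotation: np.ndarray
    translation: np.ndarray
    rms: float
    n_iterations: int
    converged: bool

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def icp_align(source: PointCloud | np.ndarray, target: PointCloud | np.ndarray,
              max_iter: int = 50, tol: float = 1e-8) -> ICPResult:
    """Point-to-point ICP: SVD rigid update per iteration, rms non-increasing.

    Stops when the rms improvement drops below ``tol`` or after
    ``max_iter`` iterations; non-convergence is flagged and the best
    transform found is returned.
    """
    src0 = source.points if isinstance(source, PointCloud) else np.asarray(source, float)
    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, float)
    tree = cKDTree(tgt)
    rotation = np.eye(3)
    translation = np.zeros(3)
    src = src0.copy()
    prev_rms = np.inf
    rms = float(np.sqrt(np.mean(tree.query(src, k=1)[0] ** 2)))
    iteration = 0
    for iteration in range(1, max_iter + 1):
        d, j = tree.query(src, k=1)
        matched = tgt[j]
        mu_s, mu_t = src.mean(axis=0), matched.mean(axis=0)
        h = (src - mu_s).T @ (matched - mu_t)
        u, _, vt = np.linalg.svd(h)
        r_step = vt.T @ u.T
        if np.linalg.det(r_step) < 0:
            vt[-1] *= -1
            r_step = vt.T @ u.T
        t_step = mu_t - r_step @ mu_s
        src = src @ r_step.T + t_step
        rotation = r_step @ rotation
        translation = r_step @ translation + t_step
        prev_rms, rms = rms, float(np.sqrt(np.mean(tree.query(src, k=1)[0] ** 2)))
        if prev_rms - rms < tol:
            break
    return ICPResult(rotation=rotation, translation=translation, rms=rms,
                     n_iterations=iteration,
                     converged=prev_rms - rms < tol or rms < tol)


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------

@dataclass
class ClassScores:
    precision: float
    recall: float
    f1: float


def segmentation_prf(predicted: np.ndarray, truth: np.ndarray,
                     classes: list[int] | None = None) -> dict[int, ClassScores]:
    """Per-class precision/recall/F1 from aligned label arrays."""
    predicted = np.asarray(predicted).ravel()
    truth = np.asarray(truth).ravel()
    if len(predicted) != len(truth):
        raise ValueError("label arrays differ in length")
    if classes is None:
        classes = sorted(set(np.unique(truth)) | set(np.unique(predicted)))
    scores = {}
    for c in classes:
        tp = int(((predicted == c) & (truth == c)).sum())
        fp = int(((predicted == c) & (truth != c)).sum())
        fn = int(((predicted != c) & (truth == c)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        scores[int(c)] = ClassScores(precision=p, recall=r, f1=f1)
    return scores


def instance_jaccard(predicted: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, dict[int, int], dict[int, float]]:
    """Jaccard matrix between predicted and true instances, plus greedy matching.

    Returns (matrix, {true id -> predicted id}, {true id -> best Jaccard});
    ids < 0 (noise/unassigned) are ignored.
    """
    predicted = np.asarray(predicted).ravel()
    truth = np.asarray(truth).ravel()
    pred_ids = [int(i) for i in np.unique(predicted) if i >= 0]
    true_ids = [int(i) for i in np.unique(truth) if i >= 0]
    matrix = np.zeros((len(true_ids), len(pred_ids)))
    for a, t in enumerate(true_ids):
        t_mask = truth == t
        for b, p in enumerate(pred_ids):
            p_mask = predicted == p
            union = (t_mask | p_mask).sum()
            matrix[a, b] = (t_mask & p_mask).sum() / union if union else 0.0
    matching: dict[int, int] = {}
    best: dict[int, float] = {}
    taken: set[int] = set()
    order = np.argsort(matrix.ravel())[::-1]
    for flat in order:
        a, b = np.unravel_index(flat, matrix.shape)
        t, p = true_ids[a], pred_ids[b]
        if t in matching or p in taken or matrix[a, b] == 0:
            continue
        matching[t] = p
        taken.add(p)
        best[t] = float(matrix[a, b])
    for t in true_ids:
        best.setdefault(t, 0.0)
    return matrix, matching, best
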