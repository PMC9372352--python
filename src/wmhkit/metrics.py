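"""Voxel- and lesion-level segmentation evaluation metrics.

Voxel level: Dice = 2TP/(2TP+FP+FN), recall = TP/(TP+FN), precision =
TP/(TP+FP), plus recall restricted to the definite-WMH mask. Lesion level:
lesions are 3D connected components (26-connectivity by default); a truth
lesion counts as detected if at least one predicted voxel overlaps it, and
lesion F1 is the harmonic mean of lesion recall and precision. Volume
agreement is the average volume difference AVD = |A-B|/B x 100%, and
boundary agreement the symmetric 95th-percentile Hausdorff distance in
physical mm (nearest-rank percentile of nearest-neighbour distances).

Empty-mask conventions: both masks empty -> perfect agreement (1 for
overlap metrics, 0 mm for Hausdorff); a ratio with an empty reference is
undefined and reported as NaN rather than a sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import as_array

__all__ = ["ConfusionCounts", "VoxelMetrics", "LesionMetrics", "MetricsReport",
           "confusion_counts", "voxel_metrics", "definite_recall",
           "lesion_metrics", "avd", "hausdorff95", "metrics_report",
           "cohort_summary"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class VoxelMetrics:
    dice: float
    recall: float
    precision: float


@dataclass(frozen=True)
class LesionMetrics:
    lesion_recall: float
    lesion_f1: float
    lesion_precision: float


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    recall: float
    precision: float
    lesion_recall: float
    lesion_f1: float
    avd_percent: float
    hausdorff95_mm: float
    definite_recall: float = float("nan")


def _binary(x) -> np.ndarray:
    return as_array(x).astype(bool)


def _check(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")


def confusion_counts(pred, truth) -> ConfusionCounts:
    p, t = _binary(pred), _binary(truth)
    _check(p, t)
    tp = int((p & t).sum())
    return ConfusionCounts(tp=tp, fp=int(p.sum()) - tp, fn=int(t.sum()) - tp)


def voxel_metrics(pred, truth) -> VoxelMetrics:
    c = confusion_counts(pred, truth)
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return VoxelMetrics(1.0, 1.0, 1.0)
    dice = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    return VoxelMetrics(dice, recall, precision)


def definite_recall(pred, definite) -> float:
    """Voxel recall restricted to the definite-WMH mask as reference."""
    p, d = _binary(pred), _binary(definite)
    _check(p, d)
    n = int(d.sum())
    if n == 0:
        return float("nan")
    return int((p & d).sum()) / n


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unsupported 3D connectivity {connectivity}")


def lesion_metrics(pred, truth, connectivity: int = 26) -> LesionMetrics:
    p, t = _binary(pred), _binary(truth)
    _check(p, t)
    struct = _structure(connectivity)
    t_lab, t_n = ndimage.label(t, structure=struct)
    p_lab, p_n = ndimage.label(p, structure=struct)
    if t_n == 0 and p_n == 0:
        return LesionMetrics(1.0, 1.0, 1.0)
    detected = np.unique(t_lab[p & t])
    detected = detected[detected > 0].size
    hits = np.unique(p_lab[p & t])
    hits = hits[hits > 0].size
    recall = detected / t_n if t_n else float("nan")
    precision = hits / p_n if p_n else float("nan")
    if np.isnan(recall) or np.isnan(precision):
        f1 = float("nan")
    elif recall + precision == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * recall * precision / (recall + precision)
    return LesionMetrics(recall, f1, precision)


def avd(pred, truth) -> float:
    """Average volume difference |A - B| / B in percent (B = truth)."""
    p, t = _binary(pred), _binary(truth)
    _check(p, t)
    b = int(t.sum())
    if b == 0:
        return float("nan")
    return abs(int(p.sum()) - b) / b * 100.0


def hausdorff95(pred, truth, spacing) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm.

    Each direction takes, over source voxels, the nearest-rank 95th
    percentile of nearest-neighbour Euclidean distances (in physical mm) to
    the other set; the result is the max of the two directions. NaN if
    either mask is empty, 0 if both are.
    """
    p, t = _binary(pred), _binary(truth)
    _check(p, t)
    if not p.any() and not t.any():
        return 0.0
    if not p.any() or not t.any():
        return float("nan")
    sp = np.asarray(spacing, dtype=np.float64)
    a = np.argwhere(p) * sp
    b = np.argwhere(t) * sp

    def directed(src, dst):
        d = cKDTree(dst).query(src, k=1)[0]
        d.sort()
        rank = max(int(np.ceil(0.95 * d.size)), 1)
        return d[rank - 1]

    return float(max(directed(a, b), directed(b, a)))


def metrics_report(pred, truth, spacing, definite=None,
                   connectivity: int = 26) -> MetricsReport:
    """Full per-subject metric suite for one binary class."""
    vm = voxel_metrics(pred, truth)
    lm = lesion_metrics(pred, truth, connectivity=connectivity)
    dr = definite_recall(pred, definite) if definite is not None else float("nan")
    return MetricsReport(dice=vm.dice, recall=vm.recall, precision=vm.precision,
                         lesion_recall=lm.lesion_recall, lesion_f1=lm.lesion_f1,
                         avd_percent=avd(pred, truth),
                         hausdorff95_mm=hausdorff95(pred, truth, spacing),
                         definite_recall=dr)


def cohort_summary(reports: dict[int, dict[str, MetricsReport]]) -> pd.DataFrame:
    """Mean +/- SD of per-subject metrics, per class.

    `reports` maps subject id -> {class name -> MetricsReport}. Cohort
    values average per-subject metrics (NaN-aware) rather than pooling
    voxels.
    """
    rows = []
    for subject, per_class in reports.items():
        for cls, rep in per_class.items():
            row = {"subject": subject, "class": cls}
            row.update(vars(rep))
            rows.append(row)
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c not in ("subject", "class")]
    agg = df.groupby("class")[metric_cols].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
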