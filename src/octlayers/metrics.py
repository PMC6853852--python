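"""Boundary and region agreement metrics.

MAD is the symmetric mean nearest-point distance between two boundary (or
mask) pixel sets; RMSE the per-column root mean squared row difference;
Dice the usual overlap coefficient. The retinal nerve fibre layer band
(RNFLT, between ILM and NFL-GCL) is additionally scored with accuracy,
sensitivity (TPR) and error rate (FPR) from the pixel confusion counts,
since nerve-fibre thickness is the key glaucoma biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError
from .segment import BOUNDARY_LABELS, LAYER_NAMES, Boundary, SegmentationResult

__all__ = [
    "mad",
    "rmse",
    "dice",
    "confusion_metrics",
    "ConfusionMetrics",
    "rnfl_mask",
    "EvalReport",
    "evaluate_result",
    "aggregate_reports",
]


def _points(obj: Boundary | np.ndarray) -> np.ndarray:
    """(row, col) coordinates of a boundary polyline or a binary mask."""
    if isinstance(obj, Boundary):
        return np.column_stack([obj.rows, np.arange(obj.rows.size)]).astype(float)
    arr = np.asarray(obj)
    if arr.dtype != bool and not np.array_equal(np.unique(arr), np.unique(arr).clip(0, 1)):
        raise UndefinedMetricError("mask must be binary")
    pts = np.argwhere(arr.astype(bool))
    return pts.astype(float)


def mad(seg: Boundary | np.ndarray, gt: Boundary | np.ndarray) -> float:
    """Symmetric mean absolute deviation between two pixel sets, in pixels.

    0.5 * (mean distance of each ground-truth point to the nearest
    segmented point + mean distance of each segmented point to the nearest
    ground-truth point), with 2D Euclidean distances.
    """
    p_seg, p_gt = _points(seg), _points(gt)
    if p_seg.size == 0 or p_gt.size == 0:
        raise UndefinedMetricError("MAD undefined for an empty point set")
    d_gt_to_seg = cKDTree(p_seg).query(p_gt)[0]
    d_seg_to_gt = cKDTree(p_gt).query(p_seg)[0]
    return 0.5 * (float(d_gt_to_seg.mean()) + float(d_seg_to_gt.mean()))


def rmse(seg: Boundary | np.ndarray, gt: Boundary | np.ndarray) -> float:
    """Root mean squared per-column row difference, in pixels."""
    r_seg = seg.rows if isinstance(seg, Boundary) else np.asarray(seg)
    r_gt = gt.rows if isinstance(gt, Boundary) else np.asarray(gt)
    if r_seg.shape != r_gt.shape:
        raise UndefinedMetricError(
            f"boundary lengths differ: {r_seg.shape} vs {r_gt.shape}"
        )
    diff = r_seg.astype(float) - r_gt.astype(float)
    return float(np.sqrt(np.mean(diff**2)))


def dice(seg_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice overlap 2|GT & SEG| / (|GT| + |SEG|) of two same-shape masks."""
    a = np.asarray(seg_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    if a.shape != b.shape:
        raise UndefinedMetricError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


class ConfusionMetrics(NamedTuple):
    accuracy: float
    sensitivity: float  # TPR
    error_rate: float  # FPR


def confusion_metrics(seg_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionMetrics:
    """Pixel-wise accuracy, sensitivity (TPR) and error rate (FPR).

    TP are region pixels labeled as region by both masks, TN background
    pixels labeled background by both; FP/FN the respective disagreements.
    A degenerate denominator (no region pixels, or no background pixels)
    makes the affected ratio undefined.
    """
    a = np.asarray(seg_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    if a.shape != b.shape:
        raise UndefinedMetricError(f"mask shapes differ: {a.shape} vs {b.shape}")
    tp = int((a & b).sum())
    tn = int((~a & ~b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: ground truth empty")
    if fp + tn == 0:
        raise UndefinedMetricError("error rate undefined: ground truth covers all pixels")
    return ConfusionMetrics(
        accuracy=(tp + tn) / (tp + fp + fn + tn),
        sensitivity=tp / (tp + fn),
        error_rate=fp / (fp + tn),
    )


def rnfl_mask(ilm: Boundary, nfl_gcl: Boundary, shape: tuple[int, int]) -> np.ndarray:
    """Nerve fibre layer band: pixels strictly between ILM and NFL-GCL."""
    rows = np.arange(shape[0])[:, None]
    return (rows > ilm.rows[None, :]) & (rows < nfl_gcl.rows[None, :])


@dataclass
class EvalReport:
    """Per-image agreement between a segmentation and ground truth."""

    boundary_mad: dict[str, float]
    boundary_rmse: dict[str, float]
    layer_dice: dict[str, float]
    rnflt: dict[str, float]  # accuracy, sensitivity, error_rate, dice

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lb in BOUNDARY_LABELS:
            rows.append(
                {"name": lb, "kind": "boundary", "mad": self.boundary_mad[lb],
                 "rmse": self.boundary_rmse[lb]}
            )
        for name in LAYER_NAMES:
            rows.append({"name": name, "kind": "layer", "dice": self.layer_dice[name]})
        rows.append({"name": "RNFLT", "kind": "rnflt", **self.rnflt})
        return pd.DataFrame(rows)


def _result_like(boundaries: dict[str, Boundary], shape: tuple[int, int]) -> SegmentationResult:
    return SegmentationResult(
        boundaries={lb: boundaries[lb] for lb in BOUNDARY_LABELS},
        shape=shape,
        order_of_extraction=[],
        path_costs={},
    )


def evaluate_result(
    result: SegmentationResult | dict[str, Boundary],
    truth: SegmentationResult | dict[str, Boundary],
    shape: tuple[int, int] | None = None,
) -> EvalReport:
    """Score one segmentation against ground-truth boundaries.

    Computes MAD and RMSE per boundary, Dice per derived layer, and the
    four RNFLT criteria. ``shape`` is required when both arguments are
    plain boundary dictionaries.
    """
    if isinstance(result, dict):
        if shape is None:
            raise ValueError("shape is required with plain boundary dictionaries")
        result = _result_like(result, shape)
    if isinstance(truth, dict):
        truth = _result_like(truth, result.shape)
    if result.shape != truth.shape:
        raise UndefinedMetricError(
            f"frame shapes differ: {result.shape} vs {truth.shape}"
        )
    b_mad = {
        lb: mad(result.boundaries[lb], truth.boundaries[lb]) for lb in BOUNDARY_LABELS
    }
    b_rmse = {
        lb: rmse(result.boundaries[lb], truth.boundaries[lb]) for lb in BOUNDARY_LABELS
    }
    l_dice = {
        name: dice(result.layer_mask(name), truth.layer_mask(name))
        for name in LAYER_NAMES
    }
    seg_band = rnfl_mask(
        result.boundaries["ILM"], result.boundaries["NFL-GCL"], result.shape
    )
    gt_band = rnfl_mask(
        truth.boundaries["ILM"], truth.boundaries["NFL-GCL"], truth.shape
    )
    cm = confusion_metrics(seg_band, gt_band)
    rnflt = {
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "error_rate": cm.error_rate,
        "dice": dice(seg_band, gt_band),
    }
    return EvalReport(b_mad, b_rmse, l_dice, rnflt)


def aggregate_reports(reports: Iterable[EvalReport]) -> pd.DataFrame:
    """Mean and standard deviation of every metric over an image set."""
    reports = list(reports)
    if not reports:
        raise UndefinedMetricError("no reports to aggregate")
    records = []
    for rep in reports:
        rec: dict[str, float] = {}
        for lb in BOUNDARY_LABELS:
            rec[f"mad/{lb}"] = rep.boundary_mad[lb]
            rec[f"rmse/{lb}"] = rep.boundary_rmse[lb]
        for name in LAYER_NAMES:
            rec[f"dice/{name}"] = rep.layer_dice[name]
        for key, val in rep.rnflt.items():
            rec[f"rnflt/{key}"] = val
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    return pd.DataFrame({"mean": frame.mean(), "std": frame.std(ddof=1 if len(reports) > 1 else 0)})
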