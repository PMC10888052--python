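"""Evaluation suite: per-region IoU, Dice, and the 95th-percentile Hausdorff distance.

Voxel-overlap metrics come from exact confusion counts.  HD95 extracts each
mask's surface (6-connectivity; voxels on the volume border count as surface),
computes both directed surface-to-surface Euclidean distance sets via
distance transforms, takes the 95th percentile of each (linear interpolation
between order statistics), and aggregates with a max — mirroring the max of
directed distances in the exact Hausdorff metric.  A flag switches to the
pooled-percentile alternative.

Degenerate conventions (flagged in the report so tables can exclude them):
both masks empty -> IoU = Dice = 1, HD95 = 0; exactly one empty -> HD95 = the
image diagonal sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .losses import REGIONS, SubregionMasks

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else 1.0  # both-empty convention


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 1.0


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary mask: voxels with a 6-neighbor outside the mask.

    The volume border counts as outside, so voxels touching it are surface.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return mask & ~interior


def _directed_surface_distances(src_surface: np.ndarray, dst_surface: np.ndarray,
                                spacing) -> np.ndarray:
    """Euclidean distance from every src surface voxel to the nearest dst surface voxel."""
    dist_to_dst = ndimage.distance_transform_edt(~dst_surface, sampling=spacing)
    return dist_to_dst[src_surface]


def image_diagonal(shape, spacing) -> float:
    return float(np.sqrt(sum((s * sp) ** 2 for s, sp in zip(shape, spacing))))


def hd95(pred: np.ndarray, truth: np.ndarray,
         spacing: tuple[float, float, float] = (1.0, 1.0, 1.0), *,
         percentile: float = 95.0, pooled: bool = False) -> tuple[float, bool]:
    """95th-percentile surface distance; returns (value, defined_flag).

    defined_flag is False for the degenerate empty-mask conventions.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p_any, t_any = pred.any(), truth.any()
    if not p_any and not t_any:
        return 0.0, False
    if p_any != t_any:
        return image_diagonal(pred.shape, spacing), False
    sp_, st = surface_voxels(pred), surface_voxels(truth)
    d_pt = _directed_surface_distances(sp_, st, spacing)
    d_tp = _directed_surface_distances(st, sp_, spacing)
    if pooled:
        value = float(np.percentile(np.concatenate([d_pt, d_tp]), percentile))
    else:
        value = float(max(np.percentile(d_pt, percentile),
                          np.percentile(d_tp, percentile)))
    return value, True


def hausdorff(pred: np.ndarray, truth: np.ndarray,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Exact (max-based) symmetric Hausdorff surface distance."""
    value, _ = hd95(pred, truth, spacing, percentile=100.0)
    return value


@dataclass
class MetricsReport:
    """Per-region metrics plus means over the regions where each is defined."""

    iou: dict[str, float]
    dice: dict[str, float]
    hd95: dict[str, float]
    defined: dict[str, bool] = field(default_factory=dict)

    def _mean(self, values: dict[str, float], need_defined: bool) -> float:
        keys = [k for k in values
                if (self.defined.get(k, True) or not need_defined)]
        if not keys:
            return float("nan")
        return float(np.mean([values[k] for k in keys]))

    @property
    def mean_iou(self) -> float:
        return self._mean(self.iou, need_defined=False)

    @property
    def mean_dice(self) -> float:
        return self._mean(self.dice, need_defined=False)

    @property
    def mean_hd95(self) -> float:
        return self._mean(self.hd95, need_defined=True)

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for k in REGIONS:
            row[f"mIoU_{k}"] = self.iou[k]
            row[f"DICE_{k}"] = self.dice[k]
            row[f"HD95_{k}"] = self.hd95[k]
        row["mIoU_Mean"] = self.mean_iou
        row["DICE_Mean"] = self.mean_dice
        row["HD95_Mean"] = self.mean_hd95
        return row


def evaluate_case(pred: SubregionMasks | np.ndarray, gt: SubregionMasks | np.ndarray,
                  spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                  ) -> MetricsReport:
    """Evaluate one case's nested (ET, TC, WT) masks against ground truth."""
    pm = pred.masks if isinstance(pred, SubregionMasks) else np.asarray(pred)
    gm = gt.masks if isinstance(gt, SubregionMasks) else np.asarray(gt)
    if pm.shape != gm.shape:
        raise ValueError(f"shape mismatch: {pm.shape} vs {gm.shape}")
    if pm.ndim == 5:  # (B, 3, H, W, D) with B == 1
        if pm.shape[0] != 1:
            raise ValueError("evaluate_case expects a single case")
        pm, gm = pm[0], gm[0]
    ious, dices, hds, defined = {}, {}, {}, {}
    for idx, region in enumerate(REGIONS):
        p, g = pm[idx].astype(bool), gm[idx].astype(bool)
        c = confusion_counts(p, g)
        overlap_defined = bool(p.any() or g.any())
        ious[region] = iou(c)
        dices[region] = dice(c)
        value, hd_defined = hd95(p, g, spacing)
        hds[region] = value
        defined[region] = overlap_defined and hd_defined
    return MetricsReport(iou=ious, dice=dices, hd95=hds, defined=defined)


def reports_to_table(case_ids: list[str], reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-case rows plus a 'Mean' summary row, in the usual ET/TC/WT column layout."""
    rows = [r.as_row() for r in reports]
    df = pd.DataFrame(rows, index=case_ids)
    df.loc["Mean"] = df.mean(axis=0)
    df.index.name = "case"
    return df.round(2)
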