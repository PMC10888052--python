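"""Sub-region training targets and the combo loss.

Brain-tumor ground truth arrives as a label map over {background, NCR, ED, ET}.
Supervision happens on three *nested* binary sub-regions:

    ET  = enhancing tumor          (label ET)
    TC  = tumor core               (ET or NCR)
    WT  = whole tumor              (TC or ED)

The combo loss is  L = L_Dice + L_WCE  where the Dice term averages the soft
Dice complement over the three regions, and the weighted cross-entropy term
weights each region k by w_k = |WT| / |k| computed per sample from the ground
truth, so the small ET region carries the largest weight.  As printed, the
WCE term has no negative-class part; alone it is minimized by predicting 1
everywhere, and it is the Dice term that penalizes false positives.  A
``full_bce`` switch adds the (1-y) ln(1-p) term for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

LABEL_BACKGROUND, LABEL_NCR, LABEL_ED, LABEL_ET = 0, 1, 2, 3
VALID_LABELS = frozenset((LABEL_BACKGROUND, LABEL_NCR, LABEL_ED, LABEL_ET))
REGIONS = ("ET", "TC", "WT")

DICE_SMOOTH = 1e-5
LOG_CLAMP = 1e-7


@dataclass
class SubregionMasks:
    """Binary nested masks, channel order (ET, TC, WT), shape (B, 3, H, W, D)."""

    masks: np.ndarray
    counts: np.ndarray  # (B, 3) voxel counts per region

    @property
    def shape(self):
        return self.masks.shape


@dataclass
class RegionWeights:
    """Per-sample loss weights w_k = |WT| / |k| (0 for empty regions)."""

    w: np.ndarray              # (B, 3)
    source_counts: np.ndarray  # (B, 3)


@dataclass
class LossValue:
    total: float
    dice_part: float
    wce_part: float
    tensor: Tensor | None = None  # graph node for backward() when inputs carried grad


def subregion_masks(labels: np.ndarray) -> SubregionMasks:
    """Derive the nested (ET, TC, WT) masks from an integer label volume.

    `labels` is (H, W, D) or (B, H, W, D) with values in {0: background,
    1: NCR, 2: ED, 3: ET}.
    """
    labels = np.asarray(labels)
    if labels.ndim == 3:
        labels = labels[None]
    if labels.ndim != 4:
        raise ValueError(f"labels must be 3D or 4D, got shape {labels.shape}")
    unknown = sorted(set(np.unique(labels).tolist()) - VALID_LABELS)
    if unknown:
        raise ValueError(f"unknown label values {unknown}; expected subset of "
                         f"{sorted(VALID_LABELS)}")
    et = labels == LABEL_ET
    tc = et | (labels == LABEL_NCR)
    wt = tc | (labels == LABEL_ED)
    masks = np.stack([et, tc, wt], axis=1)
    counts = masks.reshape(masks.shape[0], 3, -1).sum(axis=2)
    return SubregionMasks(masks=masks, counts=counts)


def region_weights(masks: SubregionMasks) -> RegionWeights:
    """w_k = |WT| / |k| per sample; empty regions get weight 0."""
    counts = masks.counts.astype(np.float64)
    wt = counts[:, 2:3]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(counts > 0, wt / counts, 0.0)
    return RegionWeights(w=w, source_counts=masks.counts)


def _as_probability_tensor(p) -> tuple[Tensor, bool]:
    if isinstance(p, Tensor):
        return p, True
    return Tensor(np.asarray(p, dtype=np.float32)), False


def _check_shapes(p: Tensor, y: np.ndarray):
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {y.shape}")


def _mask_array(y) -> np.ndarray:
    m = y.masks if isinstance(y, SubregionMasks) else np.asarray(y)
    return m.astype(np.float32)


def dice_loss(p, y, smooth: float = DICE_SMOOTH):
    """Soft Dice complement averaged over regions: 1 - (2/K) sum_k overlap_k.

    Returns a float for plain-array input, a Tensor when `p` carries autograd.
    """
    pt, is_tensor = _as_probability_tensor(p)
    ym = _mask_array(y)
    _check_shapes(pt, ym)
    B, K = ym.shape[:2]
    pf = pt.reshape(B, K, -1)
    yf = Tensor(ym.reshape(B, K, -1))
    inter = (pf * yf).sum(axis=2)
    denom = pf.sum(axis=2) + Tensor(ym.reshape(B, K, -1).sum(axis=2))
    # smoothing makes an empty region contribute overlap 1, i.e. loss term 0
    overlap = (inter * 2.0 + smooth) / (denom + smooth)
    loss = 1.0 - overlap.sum() * (1.0 / (B * K))
    return loss if is_tensor else loss.item()


def wce_loss(p, y, w: RegionWeights | np.ndarray, *, full_bce: bool = False,
             clamp: float = LOG_CLAMP):
    """Weighted cross-entropy -(1/N) sum_i sum_k w_k y_i^k ln(p_i^k).

    N is the voxel count per sample (not voxels x regions).  With
    ``full_bce=True`` the negative-class term -w_k (1-y) ln(1-p) is added.
    """
    pt, is_tensor = _as_probability_tensor(p)
    ym = _mask_array(y)
    _check_shapes(pt, ym)
    warr = w.w if isinstance(w, RegionWeights) else np.asarray(w, dtype=np.float64)
    B, K = ym.shape[:2]
    warr = np.broadcast_to(np.asarray(warr, dtype=np.float32).reshape(B, K), (B, K))
    n_vox = int(np.prod(ym.shape[2:]))
    pc = pt.clip(clamp, 1.0 - clamp)
    wy = Tensor((warr.reshape(B, K, *([1] * (ym.ndim - 2))) * ym).astype(np.float32))
    loss = -(wy * pc.log()).sum() * (1.0 / (B * n_vox))
    if full_bce:
        wny = Tensor((warr.reshape(B, K, *([1] * (ym.ndim - 2)))
                      * (1.0 - ym)).astype(np.float32))
        loss = loss - (wny * (1.0 - pc).log()).sum() * (1.0 / (B * n_vox))
    return loss if is_tensor else loss.item()


def combo_loss(p, y, *, full_bce: bool = False) -> LossValue:
    """Combo loss = Dice + WCE with Eq.-style per-sample sub-region weights."""
    pt, is_tensor = _as_probability_tensor(p)
    ym = y if isinstance(y, SubregionMasks) else _masks_from_array(y)
    w = region_weights(ym)
    d = dice_loss(pt, ym)
    c = wce_loss(pt, ym, w, full_bce=full_bce)
    total = d + c
    return LossValue(total=total.item(), dice_part=d.item(), wce_part=c.item(),
                     tensor=total if is_tensor else None)


def _masks_from_array(y: np.ndarray) -> SubregionMasks:
    m = np.asarray(y)
    counts = m.reshape(m.shape[0], m.shape[1], -1).sum(axis=2)
    return SubregionMasks(masks=m.astype(bool), counts=counts)


def dice_ce_loss(p, y) -> LossValue:
    """Unweighted baseline: Dice + per-region binary cross-entropy (both classes)."""
    pt, is_tensor = _as_probability_tensor(p)
    ym = y if isinstance(y, SubregionMasks) else _masks_from_array(y)
    B = ym.masks.shape[0]
    ones = RegionWeights(w=np.ones((B, 3)), source_counts=ym.counts)
    d = dice_loss(pt, ym)
    c = wce_loss(pt, ym, ones, full_bce=True)
    total = d + c
    return LossValue(total=total.item(), dice_part=d.item(), wce_part=c.item(),
                     tensor=total if is_tensor else None)


def dice_only_loss(p, y) -> LossValue:
    pt, is_tensor = _as_probability_tensor(p)
    ym = y if isinstance(y, SubregionMasks) else _masks_from_array(y)
    d = dice_loss(pt, ym)
    return LossValue(total=d.item(), dice_part=d.item(), wce_part=0.0,
                     tensor=d if is_tensor else None)


LOSSES = {
    "dice": dice_only_loss,
    "dice_ce": dice_ce_loss,
    "dice_wce": combo_loss,
}
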