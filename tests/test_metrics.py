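"""Overlap metrics and HD95 against hand counts and a brute-force surface oracle."""

import numpy as np
import pytest

from nlinet.losses import subregion_masks
from nlinet.metrics import (
    ConfusionCounts,
    confusion_counts,
    dice,
    evaluate_case,
    hausdorff,
    hd95,
    image_diagonal,
    iou,
    reports_to_table,
    surface_voxels,
)


# -------------------------------------------------------------- brute force
def _surface_brute(mask):
    """Boundary via explicit 6-neighbour check (volume border = background)."""
    out = np.zeros_like(mask, dtype=bool)
    idx = np.argwhere(mask)
    for x, y, z in idx:
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < mask.shape[0] and 0 <= ny < mask.shape[1]
                    and 0 <= nz < mask.shape[2]) or not mask[nx, ny, nz]:
                out[x, y, z] = True
                break
    return out


def _hd95_brute(p, y, spacing=(1.0, 1.0, 1.0)):
    """All-pairs directed surface distances, then the max of both 95th percentiles."""
    sp = np.argwhere(_surface_brute(p)) * np.asarray(spacing)
    sy = np.argwhere(_surface_brute(y)) * np.asarray(spacing)
    d = np.sqrt(((sp[:, None, :] - sy[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


# ------------------------------------------------------------- counts/ratios
def test_confusion_hand_count():
    p = np.array([1, 1, 1, 0]).reshape(1, 1, 4)
    y = np.array([1, 0, 1, 1]).reshape(1, 1, 4)
    c = confusion_counts(p, y)
    assert (c.tp, c.fp, c.fn) == (2, 1, 1)


def test_confusion_identities():
    y = np.zeros((3, 3, 3), bool)
    y[0] = True
    c = confusion_counts(y, y)
    assert (c.tp, c.fp, c.fn) == (9, 0, 0)
    c0 = confusion_counts(np.zeros_like(y), y)
    assert (c0.tp, c0.fp, c0.fn) == (0, 0, 9)
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(np.zeros((2, 2, 2)), y)


def test_iou_and_dice_arithmetic():
    c = ConfusionCounts(tp=3, fp=1, fn=2)
    assert iou(c) == pytest.approx(0.5)
    assert dice(c) == pytest.approx(6 / 9)
    perfect = ConfusionCounts(tp=5, fp=0, fn=0)
    assert iou(perfect) == dice(perfect) == 1.0
    disjoint = ConfusionCounts(tp=0, fp=4, fn=3)
    assert iou(disjoint) == dice(disjoint) == 0.0


def test_dice_iou_algebraic_identity(rng):
    for _ in range(20):
        c = ConfusionCounts(*rng.integers(0, 50, size=3))
        if c.tp + c.fp + c.fn == 0:
            continue
        assert dice(c) == pytest.approx(2 * iou(c) / (1 + iou(c)))
        assert dice(c) >= iou(c)


def test_dilation_never_improves_overlap(rng):
    from scipy import ndimage
    y = np.zeros((8, 8, 8), bool)
    y[2:5, 2:5, 2:5] = True
    p = y.copy()
    prev_iou, prev_dice = 1.0, 1.0
    for _ in range(3):
        p = ndimage.binary_dilation(p)
        c = confusion_counts(p, y)
        assert iou(c) <= prev_iou and dice(c) <= prev_dice
        prev_iou, prev_dice = iou(c), dice(c)


# ------------------------------------------------------------------- surfaces
def test_surface_matches_brute_force(rng):
    for _ in range(10):
        m = ndimage_blob(rng, size=10)
        np.testing.assert_array_equal(surface_voxels(m), _surface_brute(m))


def ndimage_blob(rng, size=10):
    from scipy import ndimage
    m = rng.random((size, size, size)) < 0.12
    m = ndimage.binary_dilation(m, iterations=1)
    return m


# ----------------------------------------------------------------------- hd95
def test_hd95_identical_masks_is_zero():
    m = np.zeros((6, 6, 6), bool)
    m[2:4, 2:4, 2:4] = True
    value, defined = hd95(m, m)
    assert value == 0.0 and defined


def test_hd95_single_voxels_axis_distance():
    p = np.zeros((12, 3, 3), bool)
    y = np.zeros((12, 3, 3), bool)
    p[2, 1, 1] = True
    y[7, 1, 1] = True
    value, defined = hd95(p, y)
    assert value == pytest.approx(5.0) and defined


def test_hd95_respects_spacing():
    p = np.zeros((6, 3, 3), bool)
    y = np.zeros((6, 3, 3), bool)
    p[1, 1, 1] = True
    y[4, 1, 1] = True
    value, _ = hd95(p, y, spacing=(2.0, 1.0, 1.0))
    assert value == pytest.approx(6.0)


def test_hd95_empty_mask_conventions():
    empty = np.zeros((4, 4, 4), bool)
    full = ~empty
    v, defined = hd95(empty, empty)
    assert v == 0.0 and not defined
    v, defined = hd95(empty, full)
    assert v == pytest.approx(image_diagonal((4, 4, 4), (1, 1, 1))) and not defined


def test_hd95_symmetry_and_bound_by_exact_hausdorff(rng):
    for _ in range(10):
        p, y = ndimage_blob(rng), ndimage_blob(rng)
        if not (p.any() and y.any()):
            continue
        v_pq, _ = hd95(p, y)
        v_qp, _ = hd95(y, p)
        assert v_pq == v_qp
        assert v_pq <= hausdorff(p, y) + 1e-12


def test_hd95_matches_all_pairs_oracle_on_random_masks(rng):
    """Distance-transform HD95 == brute-force all-pairs on 50 small mask pairs."""
    checked = 0
    while checked < 50:
        p, y = ndimage_blob(rng, 12), ndimage_blob(rng, 12)
        if not (p.any() and y.any()):
            continue
        value, defined = hd95(p, y)
        assert defined
        assert value == pytest.approx(_hd95_brute(p, y), abs=1e-9)
        checked += 1


def test_hd95_pooled_variant_differs_but_bounded(rng):
    p, y = ndimage_blob(rng), ndimage_blob(rng)
    vmax, _ = hd95(p, y)
    vpool, _ = hd95(p, y, pooled=True)
    assert vpool <= vmax + 1e-12


# ------------------------------------------------------------- case reports
def _nested_case(seed=0, shape=(10, 10, 10)):
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=int)
    labels[2:8, 2:8, 2:8] = 2
    labels[3:7, 3:7, 3:7] = 1
    labels[4:6, 4:6, 4:6] = 3
    return subregion_masks(labels)


def test_evaluate_case_perfect_prediction():
    gt = _nested_case()
    rep = evaluate_case(gt, gt)
    for region in ("ET", "TC", "WT"):
        assert rep.iou[region] == rep.dice[region] == 1.0
        assert rep.hd95[region] == 0.0
    assert rep.mean_dice == 1.0 and rep.mean_hd95 == 0.0


def test_report_mean_is_hand_average():
    gt = _nested_case()
    pred_masks = gt.masks.copy()
    pred_masks[0, 0] = False  # drop ET entirely
    rep = evaluate_case(pred_masks, gt)
    assert rep.mean_dice == pytest.approx(np.mean([rep.dice[k] for k in
                                                   ("ET", "TC", "WT")]))
    assert not rep.defined["ET"]  # empty-vs-nonempty flagged
    # undefined regions are excluded from the HD95 mean
    assert rep.mean_hd95 == pytest.approx(np.mean([rep.hd95["TC"], rep.hd95["WT"]]))


def test_batch_mean_equals_case_by_case_average():
    reports = [evaluate_case(_nested_case(s), _nested_case(s)) for s in range(5)]
    table = reports_to_table([f"c{i}" for i in range(5)], reports)
    assert len(table) == 6  # 5 cases + summary row
    assert table.loc["Mean", "DICE_Mean"] == pytest.approx(
        np.mean([r.mean_dice for r in reports]), abs=5e-3)
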