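"""Sub-region masks, weighting, and the combo loss against hand/loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlinet.losses import (
    RegionWeights,
    combo_loss,
    dice_ce_loss,
    dice_loss,
    dice_only_loss,
    region_weights,
    subregion_masks,
    wce_loss,
)
from nlinet.nn import Tensor


def _masks_for(labels):
    return subregion_masks(np.asarray(labels))


# ------------------------------------------------------------- subregion masks
def test_subregion_definitions_on_four_voxels():
    labels = np.array([0, 1, 2, 3]).reshape(1, 1, 1, 4)
    m = subregion_masks(labels).masks[0, :, 0, 0]
    np.testing.assert_array_equal(m[0], [0, 0, 0, 1])  # ET
    np.testing.assert_array_equal(m[1], [0, 1, 0, 1])  # TC = ET u NCR
    np.testing.assert_array_equal(m[2], [0, 1, 1, 1])  # WT = TC u ED


def test_all_background_gives_three_empty_masks():
    m = subregion_masks(np.zeros((2, 3, 3), dtype=int))
    assert m.masks.sum() == 0 and (m.counts == 0).all()


def test_unknown_label_is_reported():
    with pytest.raises(ValueError, match=r"\[4\]"):
        subregion_masks(np.array([[[0, 4]]]))


def test_counts_match_per_voxel_loop_oracle(rng):
    labels = rng.integers(0, 4, size=(6, 6, 6))
    m = subregion_masks(labels)
    et = tc = wt = 0
    for v in labels.ravel():  # brute-force tally with the union rules
        if v == 3:
            et += 1
        if v in (1, 3):
            tc += 1
        if v in (1, 2, 3):
            wt += 1
    np.testing.assert_array_equal(m.counts[0], [et, tc, wt])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_nesting_invariant_on_random_labels(seed):
    labels = np.random.default_rng(seed).integers(0, 4, size=(5, 5, 5))
    m = subregion_masks(labels).masks[0]
    assert not (m[0] & ~m[1]).any() and not (m[1] & ~m[2]).any()


# ------------------------------------------------------------- region weights
def test_region_weights_arithmetic():
    counts = np.array([[50, 200, 1000]])
    w = region_weights(type("M", (), {"counts": counts})()).w[0]
    np.testing.assert_allclose(w, [20.0, 5.0, 1.0])


def test_region_weights_empty_and_equal_conventions():
    empty_et = region_weights(type("M", (), {"counts": np.array([[0, 10, 10]])})())
    np.testing.assert_allclose(empty_et.w[0], [0.0, 1.0, 1.0])
    equal = region_weights(type("M", (), {"counts": np.array([[7, 7, 7]])})())
    np.testing.assert_allclose(equal.w[0], [1.0, 1.0, 1.0])


def test_weight_ordering_for_nested_counts():
    w = region_weights(type("M", (), {"counts": np.array([[3, 11, 42]])})()).w[0]
    assert w[0] >= w[1] >= w[2] == 1.0


# ----------------------------------------------------------------- dice loss
def test_dice_loss_perfect_prediction_is_zero():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[:2] = 2
    labels[0, :2] = 1
    labels[0, 0, :2] = 3
    y = _masks_for(labels)
    p = y.masks.astype(np.float32)
    assert dice_loss(p, y) < 1e-4


def test_dice_loss_total_miss_approaches_one():
    labels = np.full((3, 3, 3), 3, dtype=int)
    y = _masks_for(labels)
    assert dice_loss(np.zeros_like(y.masks, np.float32), y) > 0.999


def test_dice_loss_single_region_hand_example():
    """y = [1,1,0,0], p = [1,.5,.5,0] -> overlap 2*1.5/4 = 0.75, loss 0.25."""
    y = np.array([1, 1, 0, 0], np.float32).reshape(1, 1, 1, 1, 4)
    p = np.array([1, 0.5, 0.5, 0], np.float32).reshape(1, 1, 1, 1, 4)
    assert dice_loss(p, y, smooth=0.0) == pytest.approx(0.25, abs=1e-6)


def test_dice_loss_shape_mismatch_errors():
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros((1, 3, 2, 2, 2), np.float32),
                  np.zeros((1, 3, 2, 2, 3), np.float32))


# ------------------------------------------------------------------ wce loss
def test_wce_loss_two_voxel_hand_example():
    """N=2, one region, w=1, y=[1,0], p=[e^-1, .]: loss = 1/2."""
    y = np.array([1, 0], np.float32).reshape(1, 1, 1, 1, 2)
    p = np.array([np.exp(-1.0), 0.7], np.float32).reshape(1, 1, 1, 1, 2)
    w = np.array([[1.0]])
    assert wce_loss(p, y, w) == pytest.approx(0.5, rel=1e-5)


def test_wce_loss_perfect_positives_is_zero_and_linearity_in_w():
    labels = np.zeros((2, 2, 2), dtype=int)
    labels[0] = 3
    y = _masks_for(labels)
    p = np.clip(y.masks.astype(np.float32), 0.25, 1.0)
    w1 = region_weights(y)
    base = wce_loss(y.masks.astype(np.float32), y, w1)
    assert base == pytest.approx(0.0, abs=1e-5)
    doubled = RegionWeights(w=w1.w * 2, source_counts=w1.source_counts)
    assert wce_loss(p, y, doubled) == pytest.approx(2 * wce_loss(p, y, w1), rel=1e-5)


def test_wce_alone_is_minimized_by_all_ones_but_combo_is_not():
    """The positive-class-only cross-entropy degeneracy, and Dice's rescue."""
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0, 0, 0] = 3
    labels[0, 0, 1] = 1
    labels[0, 1, :2] = 2
    y = _masks_for(labels)
    ones = np.ones((1, 3, 4, 4, 4), np.float32)
    w = region_weights(y)
    assert wce_loss(ones, y, w) == pytest.approx(0.0, abs=1e-4)
    perfect = y.masks.astype(np.float32)
    assert combo_loss(ones, y).total > combo_loss(perfect, y).total


# ---------------------------------------------------------------- combo loss
def test_combo_is_sum_of_parts_and_matches_components():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, size=(4, 4, 4))
    y = _masks_for(labels)
    p = rng.uniform(0.01, 0.99, size=(1, 3, 4, 4, 4)).astype(np.float32)
    lv = combo_loss(p, y)
    assert lv.total == pytest.approx(lv.dice_part + lv.wce_part, rel=1e-6)
    assert lv.dice_part == pytest.approx(dice_loss(p, y), rel=1e-6)
    assert lv.wce_part == pytest.approx(wce_loss(p, y, region_weights(y)), rel=1e-6)


def test_combo_matches_per_voxel_double_loop_oracle():
    rng = np.random.default_rng(42)
    labels = rng.integers(0, 4, size=(3, 3, 3))
    y = _masks_for(labels)
    p = rng.uniform(0.05, 0.95, size=(1, 3, 3, 3, 3)).astype(np.float32)

    m = y.masks[0].astype(float)
    w = region_weights(y).w[0]
    n = 27
    dice_terms = []
    wce = 0.0
    for k in range(3):
        inter = denom = 0.0
        for idx in np.ndindex(3, 3, 3):
            yi, pi = m[k][idx], float(p[0, k][idx])
            inter += yi * pi
            denom += yi + pi
            wce -= w[k] * yi * np.log(pi)
        dice_terms.append((2 * inter + 1e-5) / (denom + 1e-5))
    expected = (1 - np.mean(dice_terms)) + wce / n

    assert combo_loss(p, y).total == pytest.approx(expected, abs=1e-6)


def test_voxel_permutation_invariance():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 4, size=(2, 2, 4))
    y = _masks_for(labels).masks.astype(np.float32)
    p = rng.uniform(0.1, 0.9, size=y.shape).astype(np.float32)
    perm = rng.permutation(16)
    y2 = y.reshape(1, 3, -1)[:, :, perm].reshape(y.shape)
    p2 = p.reshape(1, 3, -1)[:, :, perm].reshape(p.shape)
    assert combo_loss(p, y).total == pytest.approx(combo_loss(p2, y2).total, rel=1e-5)


def test_combo_decreases_along_line_toward_truth():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[:2] = 2
    labels[0, :2] = 1
    labels[0, 0, :2] = 3
    y = _masks_for(labels)
    target = y.masks.astype(np.float32)
    values = [combo_loss(np.clip(t * target, 1e-6, 1.0), y).total
              for t in (0.2, 0.4, 0.6, 0.8, 1.0)]
    assert all(b < a for a, b in zip(values, values[1:]))


def test_loss_gradients_flow_through_both_parts():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 4, size=(3, 3, 3))
    y = _masks_for(labels)
    p = Tensor(rng.uniform(0.2, 0.8, size=(1, 3, 3, 3, 3)).astype(np.float32),
               requires_grad=True)
    lv = combo_loss(p, y)
    lv.tensor.backward()
    assert p.grad is not None and np.any(p.grad != 0)


def test_loss_variants_dispatch():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 4, size=(3, 3, 3))
    y = _masks_for(labels)
    p = rng.uniform(0.1, 0.9, size=(1, 3, 3, 3, 3)).astype(np.float32)
    assert dice_only_loss(p, y).wce_part == 0.0
    assert dice_only_loss(p, y).total == pytest.approx(dice_loss(p, y), rel=1e-6)
    assert dice_ce_loss(p, y).total > dice_loss(p, y)  # adds both-class CE
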