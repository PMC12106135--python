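"""Metrics: closed forms, set-arithmetic and all-pairs-distance oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from hemaseg.metrics import (MaskPair, aggregate_folds, confusion_metrics, dice,
                             evaluate_pair, evaluate_pairs, hausdorff95, iou,
                             volumetric_similarity)


# ---------------------------------------------------------------------------
# brute-force oracles (python sets + exhaustive distances)
# ---------------------------------------------------------------------------

def mask_set(mask):
    return {tuple(ix) for ix in np.argwhere(np.asarray(mask) > 0)}


def oracle_dice(p, g):
    P, G = mask_set(p), mask_set(g)
    if not P and not G:
        return 1.0
    return 2 * len(P & G) / (len(P) + len(G))


def oracle_iou(p, g):
    P, G = mask_set(p), mask_set(g)
    if not P and not G:
        return 1.0
    return len(P & G) / len(P | G)


def oracle_vs(p, g):
    P, G = mask_set(p), mask_set(g)
    if not P and not G:
        return 1.0
    return 1 - abs(len(P) - len(G)) / (len(P) + len(G))


def oracle_boundary(mask):
    cells = mask_set(mask)
    shape = np.asarray(mask).shape
    out = set()
    for cell in cells:
        for axis in range(len(shape)):
            for d in (-1, 1):
                n = list(cell)
                n[axis] += d
                if not (0 <= n[axis] < shape[axis]) or tuple(n) not in cells:
                    out.add(cell)
    return out


def linear_percentile(values, q):
    """Hand-rolled linear-interpolation percentile between order statistics."""
    v = sorted(values)
    rank = q / 100 * (len(v) - 1)
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    return v[lo] + (rank - lo) * (v[hi] - v[lo])


def oracle_hd(p, g, percentile):
    bp, bg = oracle_boundary(p), oracle_boundary(g)
    dists = []
    for a_set, b_set in ((bp, bg), (bg, bp)):
        for a in a_set:
            dists.append(min(math.dist(a, b) for b in b_set))
    return linear_percentile(dists, percentile)


def random_pair(rng, size=16, p=0.15):
    return (rng.random((size, size)) < p).astype(np.uint8), \
           (rng.random((size, size)) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# examples
# ---------------------------------------------------------------------------

class TestDiceIoU:
    def test_perfect_overlap(self):
        m = np.eye(4, dtype=np.uint8)
        assert dice(MaskPair(m, m)) == 1.0
        assert iou(MaskPair(m, m)) == 1.0

    def test_half_overlap(self):
        p = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        g = np.array([[0, 1, 1, 0]], dtype=np.uint8)
        assert dice(MaskPair(p, g)) == 0.5
        assert np.isclose(iou(MaskPair(p, g)), 1 / 3)

    def test_disjoint_masks(self):
        p = np.array([[1, 0]], dtype=np.uint8)
        g = np.array([[0, 1]], dtype=np.uint8)
        assert dice(MaskPair(p, g)) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert dice(MaskPair(z, z)) == 1.0
        assert iou(MaskPair(z, z)) == 1.0
        assert volumetric_similarity(MaskPair(z, z)) == 1.0

    def test_algebraic_identity_iou_from_dice(self, rng):
        for _ in range(20):
            p, g = random_pair(rng)
            pair = MaskPair(p, g)
            d = dice(pair)
            assert np.isclose(iou(pair), d / (2 - d), atol=1e-12)

    def test_dice_at_least_iou(self, rng):
        for _ in range(20):
            p, g = random_pair(rng)
            pair = MaskPair(p, g)
            assert dice(pair) >= iou(pair) - 1e-12


class TestHausdorff:
    def test_single_pixel_pair_is_euclidean_distance(self):
        p = np.zeros((8, 8), dtype=np.uint8)
        g = np.zeros((8, 8), dtype=np.uint8)
        p[0, 0] = 1
        g[3, 4] = 1
        for q in (50, 95, 100):
            assert hausdorff95(MaskPair(p, g), percentile=q) == 5.0

    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        assert hausdorff95(MaskPair(m, m)) == 0.0

    def test_empty_mask_undefined(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        g = np.ones((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            hausdorff95(MaskPair(m, g))

    def test_percentile_monotone(self, rng):
        p, g = random_pair(rng)
        while not (p.any() and g.any()):
            p, g = random_pair(rng)
        pair = MaskPair(p, g)
        values = [hausdorff95(pair, percentile=q) for q in (50, 75, 95, 100)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_spacing_scales_distances(self):
        p = np.zeros((8, 8), dtype=np.uint8)
        g = np.zeros((8, 8), dtype=np.uint8)
        p[0, 0] = 1
        g[0, 4] = 1
        assert hausdorff95(MaskPair(p, g, spacing=(1.0, 0.5))) == 2.0


class TestConfusion:
    def test_identity_all_ones(self):
        m = np.eye(3, dtype=np.uint8)
        out = confusion_metrics(MaskPair(m, m))
        assert out["accuracy"] == out["sensitivity"] == out["specificity"] == 1.0

    def test_complement_prediction(self):
        g = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        out = confusion_metrics(MaskPair(1 - g, g))
        assert out["sensitivity"] == 0.0 and out["specificity"] == 0.0

    def test_printed_toy_counts(self):
        # TP=3, FP=1, FN=2, TN=10 on 16 pixels
        g = np.zeros(16, dtype=np.uint8)
        p = np.zeros(16, dtype=np.uint8)
        g[:5] = 1          # 5 positives
        p[:3] = 1          # 3 TP
        p[5] = 1           # 1 FP
        out = confusion_metrics(MaskPair(p.reshape(4, 4), g.reshape(4, 4)))
        assert np.isclose(out["sensitivity"], 0.6)
        assert np.isclose(out["specificity"], 10 / 11)
        assert np.isclose(out["accuracy"], 13 / 16)

    def test_degenerate_denominator_flagged(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        out = confusion_metrics(MaskPair(z, z))
        assert out["sensitivity"] == 1.0 and not out["sensitivity_defined"]


class TestVolumetricSimilarity:
    def test_printed_example(self):
        p = np.zeros(100, dtype=np.uint8)
        g = np.zeros(100, dtype=np.uint8)
        p[:30] = 1
        g[:50] = 1
        assert np.isclose(volumetric_similarity(MaskPair(p.reshape(10, 10),
                                                         g.reshape(10, 10))), 0.75)

    def test_equal_volumes_score_one_regardless_of_overlap(self):
        p = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        g = np.array([[0, 0, 1, 1]], dtype=np.uint8)
        assert volumetric_similarity(MaskPair(p, g)) == 1.0

    def test_empty_prediction_on_positive_gt_is_zero(self):
        p = np.zeros((2, 2), dtype=np.uint8)
        g = np.ones((2, 2), dtype=np.uint8)
        assert volumetric_similarity(MaskPair(p, g)) == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence and structural properties
# ---------------------------------------------------------------------------

def test_metrics_match_brute_force_oracles_on_random_masks(rng):
    checked_hd = 0
    for _ in range(60):
        p, g = random_pair(rng)
        pair = MaskPair(p, g)
        assert np.isclose(dice(pair), oracle_dice(p, g), atol=1e-9)
        assert np.isclose(iou(pair), oracle_iou(p, g), atol=1e-9)
        assert np.isclose(volumetric_similarity(pair), oracle_vs(p, g), atol=1e-9)
        if p.any() and g.any():
            checked_hd += 1
            assert np.isclose(hausdorff95(pair), oracle_hd(p, g, 95), atol=1e-9)
    assert checked_hd > 20


def test_overlap_metrics_invariant_to_simultaneous_transforms(rng):
    p, g = random_pair(rng)
    pair = MaskPair(p, g)
    base = (dice(pair), iou(pair), volumetric_similarity(pair))
    for op in (np.fliplr, np.flipud, np.rot90):
        moved = MaskPair(np.ascontiguousarray(op(p)), np.ascontiguousarray(op(g)))
        assert np.allclose(base, (dice(moved), iou(moved),
                                  volumetric_similarity(moved)))


def test_single_slice_stack_equals_2d(rng):
    p, g = random_pair(rng)
    while not (p.any() and g.any()):
        p, g = random_pair(rng)
    flat, stacked = MaskPair(p, g), MaskPair(p[None], g[None])
    assert dice(flat) == dice(stacked)
    assert iou(flat) == iou(stacked)
    assert volumetric_similarity(flat) == volumetric_similarity(stacked)
    # 3-D boundaries see the slice faces, distances stay in-plane
    assert np.isclose(hausdorff95(flat), hausdorff95(stacked))


class TestAggregation:
    def _fold(self, values):
        return pd.DataFrame({m: values for m in
                             ["dice", "iou", "hd95", "accuracy", "sensitivity",
                              "specificity", "vs"]}).assign(unit_id=0)

    def test_single_fold_zero_spread(self):
        out = aggregate_folds([self._fold([0.7, 0.9])], mode="slice")
        row = out[out.metric == "dice"].iloc[0]
        assert np.isclose(row["mean"], 0.8) and row["spread"] == 0.0

    def test_two_fold_means_sample_sd(self):
        out = aggregate_folds([self._fold([0.7]), self._fold([0.8])], mode="slice")
        row = out[out.metric == "dice"].iloc[0]
        assert np.isclose(row["mean"], 0.75)
        assert np.isclose(row["spread"], np.std([0.7, 0.8], ddof=1))
        assert np.isclose(row["spread"], 0.070710678, atol=1e-8)

    def test_scan_mode_uses_mean_of_fold_sds(self):
        folds = [self._fold([0.6, 0.8]), self._fold([0.5, 0.9])]
        out = aggregate_folds(folds, mode="scan")
        row = out[out.metric == "dice"].iloc[0]
        expected_spread = np.mean([np.std([0.6, 0.8], ddof=1),
                                   np.std([0.5, 0.9], ddof=1)])
        assert np.isclose(row["spread"], expected_spread)

    def test_fold_order_irrelevant(self):
        folds = [self._fold([0.7, 0.75]), self._fold([0.8]), self._fold([0.6])]
        a = aggregate_folds(folds, mode="slice")
        b = aggregate_folds(folds[::-1], mode="slice")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([self._fold([0.5]), self._fold([]).iloc[0:0]])


def test_evaluate_pairs_table_layout(rng):
    pairs = [MaskPair(*random_pair(rng)) for _ in range(5)]
    df = evaluate_pairs(pairs, unit_ids=list("abcde"), level="slice", fold=2)
    assert list(df["unit_id"]) == list("abcde")
    assert (df["fold"] == 2).all()
    for col in ("dice", "iou", "vs", "accuracy"):
        assert df[col].between(0, 1).all()


def test_mask_pair_validation():
    with pytest.raises(ValueError):
        MaskPair(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        MaskPair(np.full((2, 2), 2), np.zeros((2, 2)))
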