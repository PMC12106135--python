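"""Losses: closed-form values, brute-force distance-map oracle, combinations."""

import math

import numpy as np
import pytest

from hemaseg.autodiff import Tensor
from hemaseg.losses import (LossSpec, bce_loss, bce_with_logits_loss,
                            boundary_loss, combine, combine_from_logits,
                            dice_loss, focal_tversky_loss, make_loss,
                            parse_components, signed_distance_map)


def brute_force_sdm(mask):
    """Independent oracle: exhaustive nearest-boundary-pixel search.

    Boundary pixels are mask pixels with a 4-neighbour outside the mask
    (out-of-grid counts as background); negative inside, zero on boundary.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    boundary = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    boundary.append((i, j))
                    break
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            d = min(math.hypot(i - bi, j - bj) for bi, bj in boundary)
            if (i, j) in boundary:
                out[i, j] = 0.0
            elif mask[i, j]:
                out[i, j] = -d
            else:
                out[i, j] = d
    return out


class TestBce:
    def test_uninformative_prediction_is_ln2(self):
        probs = np.full((4, 4), 0.5)
        target = (np.arange(16).reshape(4, 4) % 2).astype(float)
        assert np.isclose(bce_loss(probs, target), math.log(2))

    def test_perfect_prediction_near_zero(self):
        target = np.array([1.0, 0.0, 1.0])
        assert bce_loss(target, target) < 1e-5

    def test_direct_evaluation(self):
        val = bce_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert np.isclose(val, -math.log(0.9), atol=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.ones(3) * 0.5, np.ones(4))

    def test_logit_form_matches_probability_form(self, rng):
        logits = rng.normal(size=(6, 6))
        target = (rng.random((6, 6)) > 0.5).astype(float)
        p = 1.0 / (1.0 + np.exp(-logits))
        assert np.isclose(bce_with_logits_loss(logits, target),
                          bce_loss(p, target), atol=1e-9)

    def test_logit_form_keeps_gradient_when_saturated(self):
        x = Tensor(np.array([[30.0, -30.0]]))
        target = np.array([[0.0, 1.0]])
        loss = bce_with_logits_loss(x, target)
        loss.backward()
        assert np.all(np.abs(x.grad) > 0.1)


class TestDice:
    def test_perfect_overlap_near_zero(self):
        m = np.array([1.0, 1.0, 0.0])
        assert dice_loss(m, m, smooth=1e-6) < 1e-5

    def test_disjoint_masks_give_one(self):
        p = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        assert np.isclose(dice_loss(p, y, smooth=0.0), 1.0)

    def test_direct_evaluation(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 0.0, 0.0])
        assert np.isclose(dice_loss(p, y, smooth=0.0), 1 / 3)


class TestFocalTversky:
    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        assert focal_tversky_loss(y, y) < 0.02

    def test_stated_formula_value(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 0.0, 0.0])
        # independent scalar evaluation: TP=1, FP=1, FN=0
        ti = (1 + 0.01) / (1 + 0.4 * 1 + 0.6 * 0 + 0.01)
        expected = (1 - ti) ** 1.0
        val = focal_tversky_loss(p, y, alpha=0.4, gamma=1.0, epsilon=0.01)
        assert np.isclose(val, expected, atol=1e-9)
        assert np.isclose(val, 0.28369, atol=1e-4)

    def test_alpha_free_when_fp_equals_fn(self):
        p = np.array([1.0, 0.0, 0.6, 0.4])
        y = np.array([0.0, 1.0, 0.6, 0.4])  # soft counts FP == FN
        v1 = focal_tversky_loss(p, y, alpha=0.2)
        v2 = focal_tversky_loss(p, y, alpha=0.8)
        assert np.isclose(v1, v2, atol=1e-9)

    def test_agrees_with_dice_at_symmetric_setting(self, rng):
        p = (rng.random(20) > 0.5).astype(float)
        y = (rng.random(20) > 0.5).astype(float)
        ft = focal_tversky_loss(p, y, alpha=0.5, gamma=1.0, epsilon=1e-9)
        dl = dice_loss(p, y, smooth=2e-9)  # 2TP+FP+FN = sum(p)+sum(y) on binary
        assert np.isclose(ft, dl, atol=1e-6)

    def test_invalid_parameters_rejected(self):
        y = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            focal_tversky_loss(y, y, alpha=1.5)
        with pytest.raises(ValueError):
            focal_tversky_loss(y, y, gamma=0.0)


class TestSignedDistanceMap:
    def test_single_pixel_against_brute_force(self):
        mask = np.zeros((7, 7))
        mask[3, 3] = 1
        sdm = signed_distance_map(mask)
        assert np.allclose(sdm, brute_force_sdm(mask), atol=1e-9)
        assert sdm[3, 3] <= 0
        assert np.isclose(sdm[3, 4], 1.0)

    def test_filled_square_interior_strictly_negative(self):
        mask = np.zeros((9, 9))
        mask[2:7, 2:7] = 1
        sdm = signed_distance_map(mask)
        assert (sdm[3:6, 3:6] < 0).all()

    def test_random_masks_match_brute_force(self, rng):
        for _ in range(5):
            mask = rng.random((7, 7)) > 0.6
            if not mask.any() or mask.all():
                continue
            assert np.allclose(signed_distance_map(mask),
                               brute_force_sdm(mask), atol=1e-9)

    def test_complement_negation_up_to_boundary_ties(self):
        mask = np.zeros((15, 15))
        mask[5:10, 6:11] = 1
        s = signed_distance_map(mask)
        sc = signed_distance_map(~mask.astype(bool))
        # The complement's boundary is offset by one pixel (and includes the
        # image frame, since out-of-grid counts as background), so negation
        # holds within sqrt(2) near the lesion boundary.
        near = (np.abs(s) <= 2.5)
        near[:3, :] = near[-3:, :] = near[:, :3] = near[:, -3:] = False
        assert near.any()
        assert np.abs(s + sc)[near].max() <= np.sqrt(2) + 1e-9

    def test_degenerate_masks_warn_and_stay_finite(self):
        with pytest.warns(UserWarning):
            empty = signed_distance_map(np.zeros((4, 4)))
        assert (empty > 0).all()
        with pytest.warns(UserWarning):
            full = signed_distance_map(np.ones((4, 4)))
        assert (full < 0).all()


class TestBoundaryLoss:
    def test_ground_truth_prediction_nonpositive(self):
        mask = np.zeros((8, 8))
        mask[2:6, 2:6] = 1
        assert boundary_loss(mask, signed_distance_map(mask)) <= 0

    def test_zero_prediction_gives_zero(self):
        mask = np.zeros((8, 8))
        mask[2:6, 2:6] = 1
        assert boundary_loss(np.zeros((8, 8)), signed_distance_map(mask)) == 0

    def test_toy_grid_hand_enumeration(self, rng):
        mask = np.zeros((3, 3))
        mask[1, 1] = 1
        sdm = brute_force_sdm(mask)
        probs = rng.random((3, 3))
        assert np.isclose(boundary_loss(probs, sdm), (probs * sdm).mean(),
                          atol=1e-12)


class TestCombine:
    def setup_method(self):
        self.rng = np.random.default_rng(5)
        self.probs = self.rng.uniform(0.05, 0.95, size=(8, 8))
        self.target = np.zeros((8, 8))
        self.target[2:5, 3:7] = 1

    def test_single_component_is_that_loss(self):
        spec = LossSpec(components=[("dice", 100.0)])
        assert np.isclose(combine(self.probs, self.target, spec),
                          dice_loss(self.probs, self.target))

    def test_even_split_is_arithmetic_mean(self):
        spec = LossSpec(components=[("bce", 50.0), ("dice", 50.0)])
        expected = 0.5 * (bce_loss(self.probs, self.target)
                          + dice_loss(self.probs, self.target))
        assert np.isclose(combine(self.probs, self.target, spec), expected)

    def test_75_25_bce_boundary_combination(self):
        spec = LossSpec(components=[("bce", 75.0), ("boundary", 25.0)])
        sdm = signed_distance_map(self.target)
        expected = (0.75 * bce_loss(self.probs, self.target)
                    + 0.25 * boundary_loss(self.probs, sdm))
        assert np.isclose(combine(self.probs, self.target, spec), expected)

    def test_boundary_without_binary_target_rejected(self):
        spec = LossSpec(components=[("boundary", 1.0)])
        with pytest.raises(ValueError, match="signed distance map"):
            combine(self.probs, self.probs, spec)

    def test_parse_components_round_trip(self):
        parsed = parse_components("bce:0.5,boundary:0.5")
        assert parsed == [("bce", 0.5), ("boundary", 0.5)]
        assert LossSpec(components=parsed).normalized == [("bce", 0.5),
                                                          ("boundary", 0.5)]

    def test_logit_combination_matches_probability_path(self):
        logits = np.log(self.probs / (1 - self.probs))
        spec = LossSpec(components=[("bce", 0.5), ("dice", 0.5)])
        assert np.isclose(combine_from_logits(logits, self.target, spec),
                          combine(self.probs, self.target, spec), atol=1e-8)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LossSpec(components=[])
        with pytest.raises(ValueError):
            LossSpec(components=[("nope", 1.0)])
        with pytest.raises(ValueError):
            LossSpec(components=[("bce", -1.0)])


@pytest.mark.parametrize("loss_name", ["bce", "dice", "focal_tversky", "boundary"])
def test_gradients_finite_on_interior_probabilities(loss_name, rng):
    """Analytic gradients match finite differences and stay finite."""
    target = np.zeros((4, 4))
    target[1:3, 1:3] = 1
    probs = rng.uniform(1e-3, 1 - 1e-3, size=(4, 4))
    spec = LossSpec(components=[(loss_name, 1.0)])
    fn = make_loss(spec)

    t = Tensor(probs)
    out = fn(t, target)
    out.backward()
    assert np.isfinite(t.grad).all()

    eps = 1e-6
    for idx in [(0, 0), (1, 1), (2, 3)]:
        pp, pm = probs.copy(), probs.copy()
        pp[idx] += eps
        pm[idx] -= eps
        num = (fn(pp, target) - fn(pm, target)) / (2 * eps)
        assert np.isclose(t.grad[idx], num, atol=1e-4)
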