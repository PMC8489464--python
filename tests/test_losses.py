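"""Loss identities: KL divergence, soft Dice, combined gradient, saliency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardiomark as cm
from cardiomark.core import LandmarkSet
from cardiomark.heatmap import encode
from cardiomark.losses import (
    combined_loss,
    kl_loss,
    loss_grad_scores,
    saliency_map,
    soft_dice_term,
    softmax_probs,
)
from cardiomark.nn import ModelConfig, UNet


def one_hot_background(shape=(8, 8), channels=4):
    t = np.zeros((channels,) + shape)
    t[0] = 1.0
    return t


class TestSoftmax:
    def test_zero_scores_uniform(self):
        probs = softmax_probs(np.zeros((1, 4, 8, 8)))
        np.testing.assert_allclose(probs, 0.25)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((1, 4, 8, 8))
        np.testing.assert_allclose(softmax_probs(s), softmax_probs(s + 3.7), atol=1e-12)

    def test_sums_to_one(self):
        s = np.random.default_rng(1).standard_normal((2, 4, 16, 16)) * 10
        np.testing.assert_allclose(softmax_probs(s).sum(axis=1), 1.0, atol=1e-6)


class TestKL:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(2)
        p = rng.random((4, 8, 8))
        p /= p.sum(0, keepdims=True)
        assert kl_loss(p, p) == 0.0

    def test_one_hot_vs_uniform_is_log4(self):
        t = one_hot_background()
        q = np.full((4, 8, 8), 0.25)
        assert kl_loss(t, q) == pytest.approx(np.log(4.0), rel=1e-12)

    def test_smoothed_truth_against_itself_is_exactly_zero(self):
        lm = LandmarkSet.from_points("SAX", [[20, 20], [40, 40], [30, 10]])
        hm = encode(lm, (64, 64), 4.0).probs
        lv = combined_loss(hm, hm)
        assert lv.kl_term == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((4, 6, 6)) + 1e-3
        q = rng.random((4, 6, 6)) + 1e-3
        p /= p.sum(0, keepdims=True)
        q /= q.sum(0, keepdims=True)
        assert kl_loss(p, q) >= 0.0


class TestSoftDice:
    def test_identical_one_hot_maps(self):
        t = np.zeros((4, 8, 8))
        t[0] = 1.0
        t[1, 2:4, 2:4] = 1.0
        t[0, 2:4, 2:4] = 0.0
        assert soft_dice_term(t, t) == pytest.approx((0.0 + 1.0 + 1.0) / 3.0, abs=1e-6)

    def test_identical_soft_maps_have_analytic_self_overlap(self):
        # soft dice of a map with itself is sum(p^2)/sum(p) per channel --
        # the self-overlap slack of non-binary maps
        rng = np.random.default_rng(3)
        p = rng.random((4, 8, 8)) + 0.1
        p /= p.sum(0, keepdims=True)
        expected = 1.0 - np.mean([
            (p[c] ** 2).sum() / (p[c].sum() + 0.5e-8) for c in range(1, 4)
        ])
        assert soft_dice_term(p, p) == pytest.approx(expected, rel=1e-6)

    def test_disjoint_supports_give_one(self):
        p = np.zeros((4, 8, 8))
        q = np.zeros((4, 8, 8))
        p[1, :4], q[1, 4:] = 1.0, 1.0
        p[2, :4], q[2, 4:] = 1.0, 1.0
        p[3, :4], q[3, 4:] = 1.0, 1.0
        assert soft_dice_term(p, q) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_half_maps(self):
        p = np.full((2, 8, 8), 0.5)
        q = np.full((2, 8, 8), 0.5)
        # dice = 2 * sum(0.25) / (sum(0.5) + sum(0.5)) = 0.5 per channel
        assert soft_dice_term(p, q) == pytest.approx(0.5, rel=1e-6)


class TestCombined:
    def test_perfect_one_hot_prediction_is_zero(self):
        t = one_hot_background()
        lv = combined_loss(t, t)
        assert lv.kl_term == 0.0
        assert lv.dice_term == pytest.approx(1.0, abs=1e-6)  # empty foreground channels
        # with a foreground landmark, a perfect one-hot match is exactly zero:
        t2 = np.zeros((4, 8, 8))
        t2[0] = 1.0
        t2[1, 3, 3] = 1.0
        t2[0, 3, 3] = 0.0
        t2[2, 5, 5] = 1.0
        t2[0, 5, 5] = 0.0
        t2[3, 1, 6] = 1.0
        t2[0, 1, 6] = 0.0
        lv2 = combined_loss(t2, t2)
        assert lv2.total == pytest.approx(0.0, abs=1e-6)

    def test_total_is_sum_of_terms(self):
        rng = np.random.default_rng(4)
        p = rng.random((4, 8, 8)) + 0.1
        q = rng.random((4, 8, 8)) + 0.1
        p /= p.sum(0, keepdims=True)
        q /= q.sum(0, keepdims=True)
        lv = combined_loss(p, q)
        assert lv.total == lv.kl_term + lv.dice_term
        assert lv.total >= lv.kl_term and lv.total >= lv.dice_term

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        p = rng.random((4, 8, 8))
        p /= p.sum(0, keepdims=True)
        s = rng.standard_normal((4, 8, 8))
        g = loss_grad_scores(p, s)
        eps = 1e-6
        idx_list = [(0, 1, 1), (1, 4, 4), (2, 0, 7), (3, 6, 2)]
        for idx in idx_list:
            sp, sm = s.copy(), s.copy()
            sp[idx] += eps
            sm[idx] -= eps
            fd = (
                combined_loss(p, softmax_probs(sp, 0)).total
                - combined_loss(p, softmax_probs(sm, 0)).total
            ) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-3, abs=1e-10)


@pytest.fixture(scope="module")
def toy():
    cfg = ModelConfig(n_levels=2, blocks_per_level=1, base_channels=4,
                      out_channels=4, input_size=(16, 16), dtype="float64")
    model = UNet(cfg, rng=9)
    rng = np.random.default_rng(6)
    image = rng.random((16, 16))
    lm = LandmarkSet("SAX", [[4, 4], [10, 12], [13, 3]], [True, True, True])
    truth = encode(lm, (16, 16), 2.0).probs
    return model, image, truth


class TestSaliency:

    def test_shape_and_finiteness(self, toy):
        model, image, truth = toy
        sal = saliency_map(model, image, truth)
        assert sal.shape == image.shape
        assert np.isfinite(sal).all()
        assert (sal >= 0).all()

    def test_matches_finite_difference_gradient(self, toy):
        model, image, truth = toy
        sal = saliency_map(model, image, truth)
        eps = 1e-6
        for (i, j) in [(4, 4), (10, 10), (0, 15)]:
            up, dn = image.copy(), image.copy()
            up[i, j] += eps
            dn[i, j] -= eps
            lu = combined_loss(truth, softmax_probs(model.forward(up[None, None]))).total
            ld = combined_loss(truth, softmax_probs(model.forward(dn[None, None]))).total
            fd = abs((lu - ld) / (2 * eps))
            assert sal[i, j] == pytest.approx(fd, rel=1e-2, abs=1e-10)
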