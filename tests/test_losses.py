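"""Loss components: spatial discounting, L1 terms, Wasserstein losses,
gradient penalty, and total assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from tomoinpaint import autodiff as ad
from tomoinpaint.losses import (LossWeights, gradient_penalty, l1_region_loss,
                                spatial_discount, total_loss, wgan_losses)


def bfs_discount_oracle(h, w, gamma):
    """gamma^l with l from a chessboard distance transform on the padded grid."""
    grid = np.zeros((h + 2, w + 2), dtype=bool)
    grid[1:-1, 1:-1] = True
    l = ndimage.distance_transform_cdt(grid, metric="chessboard")
    return (gamma ** l[1:-1, 1:-1]).astype(np.float64)


class TestSpatialDiscount:
    def test_gamma_one_is_all_ones(self):
        assert np.all(spatial_discount(5, 7, 1.0) == 1.0)

    def test_single_pixel(self):
        assert spatial_discount(1, 1, 0.99)[0, 0] == pytest.approx(0.99)

    def test_center_of_3x3(self):
        d = spatial_discount(3, 3, 0.99)
        assert d[1, 1] == pytest.approx(0.99 ** 2)
        assert d[0, 0] == pytest.approx(0.99)

    @pytest.mark.parametrize("h,w", [(1, 1), (2, 5), (7, 7), (16, 16), (33, 64)])
    def test_matches_distance_transform_oracle(self, h, w):
        assert np.allclose(spatial_discount(h, w, 0.99),
                           bfs_discount_oracle(h, w, 0.99), rtol=0, atol=1e-12)

    def test_flip_symmetric(self):
        d = spatial_discount(12, 9, 0.95)
        assert np.array_equal(d, d[::-1])
        assert np.array_equal(d, d[:, ::-1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(h=st.integers(1, 48), w=st.integers(1, 48),
           gamma=st.floats(0.5, 1.0))
    def test_rectangular_masks_match_oracle_and_symmetry(self, h, w, gamma):
        d = spatial_discount(h, w, gamma)
        assert np.allclose(d, bfs_discount_oracle(h, w, gamma), atol=1e-12)
        assert np.array_equal(d, d[::-1]) and np.array_equal(d, d[:, ::-1])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            spatial_discount(0, 3, 0.99)
        with pytest.raises(ValueError):
            spatial_discount(3, 3, 0.0)


class TestL1RegionLoss:
    def test_zero_when_predictions_equal_truth(self):
        x = np.full((4, 4), 0.3)
        region = np.ones((4, 4), dtype=bool)
        assert l1_region_loss(x, x, x, region) == 0.0

    def test_hand_computed_single_pixel(self):
        region = np.array([[True]])
        v = l1_region_loss(np.array([[0.6]]), np.array([[0.5]]), np.array([[0.5]]),
                           region, discount=np.array([[0.99]]))
        assert v == pytest.approx(0.99 * 0.1, abs=1e-12)

    def test_coarse_term_is_linear(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(size=(6, 6))
        fine = truth.copy()
        coarse = truth + 0.1
        region = np.ones((6, 6), dtype=bool)
        v1 = l1_region_loss(coarse, fine, truth, region)
        v2 = l1_region_loss(truth + 0.2, fine, truth, region)
        assert v2 == pytest.approx(2 * v1)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            l1_region_loss(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)),
                           np.zeros((2, 2), dtype=bool))


class TestWganLosses:
    def test_identical_scores_zero_critic_loss(self):
        c, _ = wgan_losses([1.0, 2.0], [1.0, 2.0])
        assert c == 0.0

    def test_sign_conventions(self):
        c, g = wgan_losses([5.0, 5.0], [2.0, 2.0])
        assert c == pytest.approx(-3.0)
        assert g == pytest.approx(-2.0)

    def test_shift_invariance_of_critic_loss(self):
        rng = np.random.default_rng(1)
        r, f = rng.normal(size=8), rng.normal(size=8)
        c0, _ = wgan_losses(r, f)
        c1, _ = wgan_losses(r + 7.5, f + 7.5)
        assert c1 == pytest.approx(c0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        r, f = rng.normal(size=9), rng.normal(size=9)
        c0, g0 = wgan_losses(r, f)
        c1, g1 = wgan_losses(rng.permutation(r), rng.permutation(f))
        assert (c0, g0) == pytest.approx((c1, g1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wgan_losses([], [1.0])


class TestGradientPenalty:
    @pytest.mark.parametrize("c", [0.0, 0.5, 1.0, 3.0])
    def test_linear_critic_closed_form(self, c):
        """critic(x) = c*x has gradient norm |c|: penalty = lambda(|c|-1)^2."""
        def critic(x):
            return x * c

        rng = np.random.default_rng(0)
        real = rng.normal(size=(6, 1)).astype(np.float64)
        fake = rng.normal(size=(6, 1)).astype(np.float64)
        got = float(gradient_penalty(critic, real, fake, 10.0, rng).data)
        expected = 10.0 * (abs(c) - 1.0) ** 2
        assert got == pytest.approx(expected, rel=1e-6, abs=1e-6)

    def test_unit_slope_multivariate_critic_zero_penalty(self):
        n = 4
        w = np.full((n, 1), 1.0 / np.sqrt(n))

        def critic(x):
            return x @ ad.Tensor(w)

        rng = np.random.default_rng(1)
        real = rng.normal(size=(5, n))
        fake = rng.normal(size=(5, n))
        assert float(gradient_penalty(critic, real, fake, 10.0, rng).data) == \
            pytest.approx(0.0, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            gradient_penalty(lambda x: x, np.ones((2, 2)), np.ones((3, 2)), 1.0, rng)


class TestTotalLoss:
    def test_all_zero(self):
        bd = total_loss(0, 0, 0, 0, 0)
        assert bd.total == 0.0

    def test_all_ones_at_default_weights(self):
        bd = total_loss(1, 1, 1, 1, 1)
        assert bd.total == pytest.approx(13.401, abs=1e-9)
        assert bd.generator_total == pytest.approx(1.2 + 1.2 + 0.001, abs=1e-12)
        assert bd.critic_total == pytest.approx(11.0, abs=1e-12)

    def test_reduction_when_generator_terms_ignored(self):
        w = LossWeights(alpha_mask=1e-300, alpha_fov=1e-300, alpha_gan=1e-300)
        bd = total_loss(1, 1, 1, 0.4, 0.2, w)
        assert bd.total == pytest.approx(0.4 + 10 * 0.2)

    def test_nan_component_rejected(self):
        with pytest.raises(ValueError):
            total_loss(float("nan"), 0, 0, 0, 0)
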