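"""Generator/critic contracts: paste semantics, determinism, attention."""

import time

import numpy as np
import pytest

from tomoinpaint import ModelConfig, place_mask
from tomoinpaint.model import (Critic, EmptyBackgroundError, InpaintModel,
                               MeanFillInpainter, OracleInpainter,
                               attention_weights)

from conftest import flat_image


@pytest.fixture(scope="module")
def model():
    return InpaintModel(ModelConfig.tiny(seed=3))


@pytest.fixture(scope="module")
def patch(model):
    rng = np.random.default_rng(5)
    img = flat_image(96, 96, 0.5)
    px = img.pixels + 0.2 * rng.uniform(size=img.pixels.shape)
    px = np.clip(px, 0.01, 1.0)
    from tomoinpaint import GrayImage

    return place_mask(GrayImage(px), (16, 16), 64, 16, position="center")


class TestComplete:
    def test_blended_outside_mask_is_bit_exact(self, model, patch):
        res = model.complete(patch)
        outside = ~patch.mask
        assert np.array_equal(res.blended[outside], patch.truth_network()[outside])

    def test_deterministic(self, model, patch):
        a = model.complete(patch)
        b = model.complete(patch)
        assert np.array_equal(a.fine, b.fine)
        assert np.array_equal(a.coarse, b.coarse)

    def test_outputs_within_network_domain(self, model, patch):
        res = model.complete(patch)
        for arr in (res.coarse, res.fine, res.blended):
            assert arr.shape == (64, 64)
            assert arr.min() >= -1.0 and arr.max() <= 1.0

    def test_shape_mismatch_rejected(self, model):
        bad = place_mask(flat_image(128, 128, 0.5), (0, 0), 128, 16, position="center")
        with pytest.raises(ValueError):
            model.complete(bad)

    def test_attention_branch_is_live(self, patch):
        m = InpaintModel(ModelConfig.tiny(seed=3))
        with_attn = m.complete(patch)
        m.generator.use_attention = False
        without = m.complete(patch)
        assert not np.array_equal(with_attn.fine, without.fine)


class TestAttentionWeights:
    def test_single_background_patch_gets_weight_one(self):
        fg = np.random.default_rng(0).normal(size=(9, 5))
        bg = np.random.default_rng(1).normal(size=(9, 1))
        w = attention_weights(fg, bg)
        assert np.allclose(w, 1.0)

    def test_identical_background_patches_share_weight(self):
        fg = np.random.default_rng(0).normal(size=(9, 4))
        one = np.random.default_rng(1).normal(size=(9, 1))
        bg = np.repeat(one, 6, axis=1)
        w = attention_weights(fg, bg)
        assert np.allclose(w, 1.0 / 6)

    def test_rows_normalized(self):
        rng = np.random.default_rng(2)
        w = attention_weights(rng.normal(size=(12, 20)), rng.normal(size=(12, 7)))
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-5)

    def test_empty_background_rejected(self):
        with pytest.raises(EmptyBackgroundError):
            attention_weights(np.ones((9, 3)), np.ones((9, 0)))


class TestCritics:
    def test_identical_inputs_identical_scores(self, model, patch):
        res = model.complete(patch)
        crop = res.blended[patch.spec.mask_slices()]
        a = model.criticize(res.blended, crop)
        b = model.criticize(res.blended, crop)
        assert a == b

    def test_finite_scores_for_extreme_inputs(self, model):
        for v in (-1.0, 1.0):
            s = model.criticize(np.full((64, 64), v), np.full((16, 16), v))
            assert np.isfinite(s.local) and np.isfinite(s.global_)

    def test_512_fov_global_path_matches_256_feature_length(self):
        """The extra stride-2 input conv restores the 256-path dimensionality."""
        rng = np.random.default_rng(0)
        c256 = Critic(256, width=4, rng=rng)
        c512 = Critic(512, width=4, rng=rng, extra_input_conv=True)
        assert c256.n_features == c512.n_features

    def test_local_crop_centered_and_clipped(self, model):
        spec = place_mask(flat_image(64, 64, 0.5), (0, 0), 64, 16,
                          position="center").spec
        ys, xs = model.local_crop_slices(spec)
        assert ys.stop - ys.start == model.cfg.local_crop_side
        # centered mask at offset (24,24): crop centered on (32,32)
        assert ys.start == 24 and xs.start == 24


class TestCheckpointRoundtrip:
    def test_save_load_preserves_every_parameter(self, model, tmp_path):
        model.save(tmp_path / "w.npz")
        back = InpaintModel.load(tmp_path / "w.npz")
        for (ka, a), (kb, b) in zip(sorted(model.named_params().items()),
                                    sorted(back.named_params().items())):
            assert ka == kb
            assert np.array_equal(a.data, b.data)

    def test_load_rejects_incompatible_shapes(self, model, tmp_path):
        model.save(tmp_path / "w.npz")
        other = InpaintModel(ModelConfig.tiny(seed=3))
        p = next(iter(other.named_params().values()))
        p.data = np.zeros((1, 1, 1, 1), dtype=np.float32)
        # corrupt the saved file with the wrong-shape parameter set
        import json

        import numpy as _np

        _np.savez(tmp_path / "w.npz", **{k: v.data for k, v in other.named_params().items()})
        with pytest.raises(ValueError):
            InpaintModel.load(tmp_path / "w.npz")


class TestReferenceInpainters:
    def test_oracle_reproduces_truth_exactly(self, patch):
        res = OracleInpainter(64).complete(patch)
        assert np.array_equal(res.blended, patch.truth_network())

    def test_mean_fill_uses_known_mean(self):
        patch = place_mask(flat_image(64, 64, 0.75), (0, 0), 64, 16, position="center")
        res = MeanFillInpainter(64).complete(patch)
        assert np.allclose(res.blended[patch.mask], 0.5, atol=1e-6)  # 0.75 -> 0.5
        assert np.array_equal(res.blended[~patch.mask],
                              patch.truth_network()[~patch.mask])


def test_tiny_forward_backward_under_one_second(model, patch):
    """Desk-scale config completes a forward+backward pass quickly on CPU."""
    from tomoinpaint import autodiff as ad

    truth = patch.truth_network()[None, None]
    masks = patch.mask[None]
    t0 = time.time()
    coarse, fine, blended = model.complete_batch(truth, masks)
    ad.tmean(ad.absolute(fine - ad.Tensor(truth))).backward()
    assert time.time() - t0 < 1.0
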