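"""Sliding-window heatmap semantics against brute-force recomputation."""

import numpy as np
import pytest

from tomoinpaint import GrayImage, place_mask
from tomoinpaint.heatmap import (METRICS, _window_origins, averaged_heatmap,
                                 score_patch, sliding_heatmap, sliding_heatmaps)
from tomoinpaint.model import MeanFillInpainter, OracleInpainter
from tomoinpaint.autodiff import softplus


def brute_force_heatmaps(model, image, fov, mask_side, stride, averaged):
    """Independent per-position re-crop, re-mask, re-score loop."""
    h, w = image.height, image.width
    values = {m: np.zeros((h, w)) for m in METRICS}
    acc = {m: np.zeros((h, w)) for m in METRICS}
    coverage = np.zeros((h, w), dtype=np.int64)
    for oy in range(0, h - fov + 1, stride):
        for ox in range(0, w - fov + 1, stride):
            masked = place_mask(image, (oy, ox), fov, mask_side, position="center")
            res = model.complete(masked)
            scores = model.criticize(res.blended, res.blended[masked.spec.mask_slices()])
            truth = masked.truth_network()
            mse = float(((res.blended[masked.mask].astype(np.float64)
                          - truth[masked.mask]) ** 2).mean()) / 4.0
            discr = float(softplus(-scores.global_))
            vals = {"MSE": mse, "DISCR": discr, "DMSE": mse * discr}
            my, mx = masked.spec.mask_slices()
            foot = (slice(oy + my.start, oy + my.stop), slice(ox + mx.start, ox + mx.stop))
            coverage[foot] += 1
            for m in METRICS:
                values[m][foot] = vals[m]
                acc[m][foot] += vals[m]
    covered = coverage > 0
    if averaged:
        out = {m: np.divide(acc[m], coverage, out=np.zeros_like(acc[m]),
                            where=covered) for m in METRICS}
    else:
        out = values
    return out, coverage


@pytest.fixture(scope="module")
def phantom_96(small_phantom_module=None):
    from tomoinpaint import PhantomParams, generate_phantom

    params = PhantomParams(height=96, width=96, texture_sigma=4.0, n_vessels=2,
                           edge_margin=0)
    img, _ = generate_phantom(params, np.random.default_rng(77))
    return img


def test_window_origin_arithmetic():
    assert list(_window_origins(272, 256, 8)) == [0, 8, 16]
    assert len(list(_window_origins(96, 64, 8))) == 5


class TestScorePatch:
    def test_oracle_gives_zero_mse_and_dmse(self, phantom_96):
        patch = place_mask(phantom_96, (10, 10), 64, 16, position="center")
        oracle = OracleInpainter(64)
        assert score_patch(oracle, patch, "MSE") == 0.0
        assert score_patch(oracle, patch, "DMSE") == 0.0
        assert score_patch(oracle, patch, "DISCR") > 0.0

    def test_dmse_is_product_of_mse_and_discr(self, phantom_96, tiny_model):
        patch = place_mask(phantom_96, (20, 4), 64, 16, position="center")
        mse = score_patch(tiny_model, patch, "MSE")
        discr = score_patch(tiny_model, patch, "DISCR")
        dmse = score_patch(tiny_model, patch, "DMSE")
        assert dmse == pytest.approx(mse * discr, rel=1e-12)

    def test_unknown_metric_rejected(self, phantom_96, tiny_model):
        patch = place_mask(phantom_96, (0, 0), 64, 16, position="center")
        with pytest.raises(ValueError):
            score_patch(tiny_model, patch, "SSIM")


class TestSlidingHeatmap:
    def test_matches_brute_force_bit_exact(self, phantom_96, tiny_model):
        for averaged in (False, True):
            maps = sliding_heatmaps(tiny_model, phantom_96, 64, 16, stride=8,
                                    averaged=averaged)
            ref, coverage = brute_force_heatmaps(tiny_model, phantom_96, 64, 16,
                                                 8, averaged)
            for m in METRICS:
                assert np.array_equal(maps[m].values, ref[m]), (m, averaged)
            valid_expected = (coverage > 0) & phantom_96.tissue_mask()
            assert np.array_equal(maps["MSE"].valid, valid_expected)

    def test_oracle_heatmap_zero_on_valid_region(self, phantom_96):
        hmap = sliding_heatmap(OracleInpainter(64), phantom_96, 64, 16,
                               stride=8, metric="MSE")
        assert np.all(hmap.values[hmap.valid] == 0.0)

    def test_values_nonnegative_everywhere_valid(self, phantom_96, tiny_model):
        maps = sliding_heatmaps(tiny_model, phantom_96, 64, 16, stride=16)
        for m in METRICS:
            assert np.all(maps[m].values[maps[m].valid] >= 0.0)

    def test_border_band_invalid(self, phantom_96, tiny_model):
        hmap = sliding_heatmap(tiny_model, phantom_96, 64, 16, stride=8, metric="MSE")
        # center mask offset 24: first written row/col is 24
        assert not hmap.valid[:24].any()
        assert not hmap.valid[:, :24].any()

    def test_deterministic_given_weights(self, phantom_96, tiny_model):
        a = sliding_heatmap(tiny_model, phantom_96, 64, 16, stride=16, metric="DMSE")
        b = sliding_heatmap(tiny_model, phantom_96, 64, 16, stride=16, metric="DMSE")
        assert np.array_equal(a.values, b.values)

    def test_image_smaller_than_fov_rejected(self, tiny_model):
        img = GrayImage(np.full((32, 32), 0.5))
        with pytest.raises(ValueError):
            sliding_heatmap(tiny_model, img, 64, 16)


class TestAveragedHeatmap:
    def test_single_window_equals_non_averaged(self, tiny_model):
        from tomoinpaint import PhantomParams, generate_phantom

        params = PhantomParams(height=64, width=64, texture_sigma=4.0,
                               n_vessels=1, edge_margin=0)
        img, _ = generate_phantom(params, np.random.default_rng(2))
        plain = sliding_heatmap(tiny_model, img, 64, 16, stride=8, metric="MSE")
        avg = averaged_heatmap(tiny_model, img, 64, 16, stride=8, metric="MSE")
        assert np.array_equal(plain.values, avg.values)

    def test_two_window_overlap_averages(self, phantom_96, tiny_model):
        """A pixel covered by windows with scores a and b reads (a+b)/2."""
        # stride 8, mask 16: mask footprints at offsets 24.. overlap by 8 px
        avg = averaged_heatmap(tiny_model, phantom_96, 64, 16, stride=8, metric="MSE")
        ref, coverage = brute_force_heatmaps(tiny_model, phantom_96, 64, 16, 8, True)
        two = coverage == 2
        assert two.any()
        assert np.array_equal(avg.values[two], ref["MSE"][two])

    def test_coverage_counts_match_brute_force(self, phantom_96):
        # cheap model: oracle (scores all zero) — counts are model-independent
        _, coverage = brute_force_heatmaps(OracleInpainter(64), phantom_96,
                                           64, 16, 8, True)
        expected = np.zeros((96, 96), dtype=np.int64)
        for oy in range(0, 33, 8):
            for ox in range(0, 33, 8):
                expected[oy + 24:oy + 40, ox + 24:ox + 40] += 1
        assert np.array_equal(coverage, expected)
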