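"""CAM explainers against analytic cases and independently coded oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from hmcnet import autodiff as ad
from hmcnet.autodiff import Tensor
from hmcnet.cam import (
    grad_cam,
    grad_cam_pp,
    gradcampp_pixel_weights,
    localization_iou,
    mean_iou,
    minmax_normalize,
    normalize_resize,
    score_cam,
)
from hmcnet.errors import InputError
from hmcnet.network import BackboneConfig, build_model


class HeadModel:
    """Duck-typed stand-in exposing the explainer interface: the target
    feature maps are a function of the input, the head maps them to logits."""

    def __init__(self, feat_fn, head_fn, num_classes=3):
        self.config = SimpleNamespace(num_classes=num_classes)
        self.feat_fn = feat_fn
        self.head_fn = head_fn

    def eval(self):
        return self

    def zero_grad(self):
        pass

    def forward_stages(self, image):
        x = Tensor(np.asarray(image, np.float32), requires_grad=True)
        feats = self.feat_fn(x)
        return {"x4p": feats, "logits": self.head_fn(feats)}

    def __call__(self, batch):  # Score-CAM passes masked batches through
        x = Tensor(np.asarray(batch, np.float32))
        return self.head_fn(self.feat_fn(x))


def identity_feats(x):
    # a grad-capturing node whose value equals the input's first channel block
    return ad.add(x, np.float32(0.0))


def sum_head(sign=1.0):
    def head(feats):
        B, C, H, W = feats.data.shape
        pooled = ad.global_avg_pool(feats)  # (B, C)
        ones = np.full((C, 3), sign * H * W, np.float32)
        return ad.matmul(pooled, ones)

    return head


class TestGradCam:
    def test_global_sum_head_gives_normalized_relu_of_map(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((1, 1, 6, 6)).astype(np.float32)
        model = HeadModel(identity_feats, sum_head(+1.0), num_classes=3)
        hm, inter = grad_cam(model, img[0], 0, return_intermediates=True)
        np.testing.assert_allclose(inter.G, 1.0, atol=1e-6)
        np.testing.assert_allclose(inter.channel_weights, 1.0, atol=1e-6)
        np.testing.assert_allclose(hm.values, minmax_normalize(np.maximum(img[0, 0], 0)), atol=1e-6)

    def test_all_negative_gradients_give_zero_heatmap(self):
        rng = np.random.default_rng(1)
        img = np.abs(rng.standard_normal((1, 1, 5, 5))).astype(np.float32)
        model = HeadModel(identity_feats, sum_head(-1.0))
        hm = grad_cam(model, img[0], 0)
        np.testing.assert_array_equal(hm.values, 0.0)

    def test_alpha_matches_finite_difference_of_head(self):
        rng = np.random.default_rng(2)
        A0 = rng.standard_normal((1, 4, 3, 3)).astype(np.float32)
        w = rng.standard_normal((4, 3)).astype(np.float32) * 0.3

        def head(feats):
            return ad.matmul(ad.global_avg_pool(feats), Tensor(w))

        model = HeadModel(identity_feats, head)
        _, inter = grad_cam(model, A0[0], 1, return_intermediates=True)

        def y_c(a):
            pooled = a.mean(axis=(2, 3))
            return float((pooled @ w.astype(np.float64))[0, 1])

        eps = 1e-2
        for k in range(4):
            up, dn = A0.copy(), A0.copy()
            up[0, k] += eps
            dn[0, k] -= eps
            fd = (y_c(up) - y_c(dn)) / (2 * eps) / A0.shape[2] / A0.shape[3]
            assert inter.channel_weights[k] == pytest.approx(fd, abs=1e-3)

    def test_class_index_out_of_range(self):
        model = HeadModel(identity_feats, sum_head())
        with pytest.raises(InputError):
            grad_cam(model, np.zeros((1, 2, 2), np.float32), 5)

    def test_real_network_heatmap_is_valid(self):
        cfg = BackboneConfig(stage_channels=(8, 8, 16, 16, 16), input_size=32,
                             width_divisor=1, blocks=(1, 1, 1, 1))
        model = build_model("hmc", cfg, seed=0)
        img = np.random.default_rng(3).uniform(-1, 1, (3, 32, 32)).astype(np.float32)
        hm = grad_cam(model, img, 0)
        assert hm.values.shape == (32, 32)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0


def literal_gradcampp_oracle(A, G):
    """Independently coded closed form, explicit loops (float64)."""
    A = A.astype(np.float64)
    G = G.astype(np.float64)
    C, H, W = A.shape
    cam = np.zeros((H, W))
    for k in range(C):
        sum_a = A[k].sum()
        wk = 0.0
        for i in range(H):
            for j in range(W):
                g = G[k, i, j]
                denom = 2.0 * g * g + sum_a * g**3
                alpha = 0.0 if denom == 0.0 else g * g / denom
                wk += alpha * max(g, 0.0)
        cam += wk * A[k]
    return np.maximum(cam, 0.0)


class TestGradCamPP:
    def test_zero_gradients_give_zero_heatmap(self):
        img = np.zeros((1, 1, 4, 4), np.float32)

        def dead_head(feats):
            B = feats.data.shape[0]
            return ad.mul(ad.matmul(ad.global_avg_pool(feats), np.zeros((1, 3), np.float32)),
                          np.float32(0.0))

        model = HeadModel(identity_feats, dead_head)
        hm = grad_cam_pp(model, img[0], 0)
        np.testing.assert_array_equal(hm.values, 0.0)

    def test_constant_map_constant_gradient_closed_form(self):
        a, g, H, W = 2.0, 3.0, 4, 5
        A = np.full((1, H, W), a, np.float32)
        G = np.full((1, H, W), g, np.float32)
        alpha = gradcampp_pixel_weights(A, G)
        # alpha_ij = g^2/(2 g^2 + HW a g^3) = 1/(2 + HW * a * g)
        np.testing.assert_allclose(alpha, 1.0 / (2.0 + H * W * a * g), atol=1e-6)

    def test_matches_independent_literal_oracle(self):
        rng = np.random.default_rng(4)
        A0 = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        w = rng.standard_normal((3, 3)).astype(np.float32) * 0.4

        def head(feats):
            return ad.matmul(ad.global_avg_pool(feats), Tensor(w))

        model = HeadModel(identity_feats, head)
        hm, inter = grad_cam_pp(model, A0[0], 2, return_intermediates=True)
        oracle_cam = literal_gradcampp_oracle(inter.A, inter.G)
        np.testing.assert_allclose(
            hm.values, minmax_normalize(oracle_cam.astype(np.float32)), atol=1e-5
        )

    def test_literal_eq24_drops_relu_factor(self):
        rng = np.random.default_rng(5)
        A0 = rng.standard_normal((1, 2, 3, 3)).astype(np.float32)
        w = rng.standard_normal((2, 3)).astype(np.float32)

        def head(feats):
            return ad.matmul(ad.global_avg_pool(feats), Tensor(w))

        model = HeadModel(identity_feats, head)
        _, default = grad_cam_pp(model, A0[0], 0, return_intermediates=True)
        _, literal = grad_cam_pp(model, A0[0], 0, literal_eq24=True, return_intermediates=True)
        np.testing.assert_allclose(literal.channel_weights,
                                   default.alpha_ij.sum(axis=(1, 2)), atol=1e-6)


class TestScoreCam:
    def constant_logit_model(self):
        def head(feats):
            B = feats.data.shape[0]
            zeros = ad.mul(ad.global_avg_pool(feats), np.float32(0.0))  # (B, C)
            C = zeros.data.shape[1]
            return ad.matmul(zeros, np.zeros((C, 3), np.float32))  # all-zero logits

        return HeadModel(identity_feats, head)

    def test_constant_logits_weight_all_channels_equally(self):
        rng = np.random.default_rng(6)
        img = rng.standard_normal((3, 5, 5)).astype(np.float32)
        model = self.constant_logit_model()
        hm, inter = score_cam(model, img, 0, return_intermediates=True)
        np.testing.assert_allclose(inter.channel_weights, 1 / 3, atol=1e-6)
        expected = minmax_normalize(np.maximum(img.sum(axis=0) / 3, 0.0))
        np.testing.assert_allclose(hm.values, expected, atol=1e-5)

    def test_single_channel_positive_score_is_normalized_relu(self):
        rng = np.random.default_rng(7)
        img = rng.standard_normal((1, 6, 6)).astype(np.float32)

        def head(feats):  # positive score for class 0 regardless of input
            pooled = ad.global_avg_pool(feats)
            z = ad.mul(pooled, np.float32(0.0))
            return ad.add(z, np.array([[2.0]], np.float32) @ np.ones((1, 1), np.float32))

        model = HeadModel(identity_feats, head, num_classes=1)
        hm = score_cam(model, img, 0)
        np.testing.assert_allclose(
            hm.values, minmax_normalize(np.maximum(img[0], 0.0)), atol=1e-5
        )

    def test_constant_feature_channel_gets_zero_mask(self):
        img = np.full((1, 4, 4), 0.7, np.float32)
        model = self.constant_logit_model()
        _, inter = score_cam(model, img, 0, return_intermediates=True)
        np.testing.assert_array_equal(inter.masks, 0.0)

    def test_result_independent_of_chunk_size(self):
        cfg = BackboneConfig(stage_channels=(8, 8, 16, 16, 16), input_size=32,
                             width_divisor=1, blocks=(1, 1, 1, 1))
        model = build_model("hmc", cfg, seed=1)
        img = np.random.default_rng(8).uniform(-1, 1, (3, 32, 32)).astype(np.float32)
        a = score_cam(model, img, 1, chunk_size=3).values
        b = score_cam(model, img, 1, chunk_size=16).values
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_invariant_to_positive_rescaling_of_scores(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((4, 5, 5)).astype(np.float32)
        s = rng.uniform(0.1, 1.0, 4)
        cam1 = minmax_normalize(np.maximum((s[:, None, None] * A).sum(0), 0))
        cam2 = minmax_normalize(np.maximum((7.5 * s[:, None, None] * A).sum(0), 0))
        np.testing.assert_allclose(cam1, cam2, atol=1e-6)


class TestNormalizeResize:
    def test_minmax_arithmetic(self):
        out = normalize_resize(np.array([[0.0, 2.0, 4.0]]), (1, 3))
        np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]], atol=1e-6)

    def test_constant_input_gives_zeros(self):
        out = normalize_resize(np.full((3, 3), 9.0), (6, 6))
        np.testing.assert_array_equal(out, 0.0)

    def test_output_size_224(self):
        out = normalize_resize(np.random.default_rng(0).uniform(0, 1, (7, 7)), (224, 224))
        assert out.shape == (224, 224)
        assert out.min() == 0.0 and out.max() == 1.0


class TestLocalizationIoU:
    def test_identical_binarization_scores_one(self):
        mask = np.zeros((10, 10), bool)
        mask[2:6, 2:6] = True
        heat = mask.astype(np.float32)
        assert localization_iou(heat, mask) == 1.0

    def test_disjoint_regions_score_zero(self):
        mask = np.zeros((10, 10), bool)
        mask[:3, :3] = True
        heat = np.zeros((10, 10), np.float32)
        heat[7:, 7:] = 1.0
        assert localization_iou(heat, mask) == 0.0

    def test_half_overlapping_rectangles_score_one_third(self):
        # two 4x8 rectangles overlapping on half their area
        mask = np.zeros((16, 16), bool)
        mask[4:8, 0:8] = True
        heat = np.zeros((16, 16), np.float32)
        heat[4:8, 4:12] = 1.0
        # pixel-count oracle
        inter = (mask & (heat >= 0.5)).sum()
        union = (mask | (heat >= 0.5)).sum()
        assert inter / union == pytest.approx(1 / 3)
        assert localization_iou(heat, mask) == pytest.approx(1 / 3)

    def test_mask_resampled_to_heatmap_resolution(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        heat = np.zeros((10, 10), np.float32)
        heat[2:8, 2:8] = 1.0
        # oracle: resample the mask by the same half-pixel-center rule and count
        idx = ((np.arange(10) + 0.5) * 2).astype(int)
        small = mask[np.ix_(idx, idx)]
        pred = heat >= 0.5
        expected = (small & pred).sum() / (small | pred).sum()
        assert localization_iou(heat, mask) == pytest.approx(expected)

    def test_non_binary_mask_raises(self):
        with pytest.raises(InputError):
            localization_iou(np.zeros((4, 4)), np.full((4, 4), 0.3))

    def test_threshold_range_enforced(self):
        with pytest.raises(InputError):
            localization_iou(np.zeros((4, 4)), np.zeros((4, 4), bool), threshold=1.5)

    def test_mean_iou_is_arithmetic_mean(self):
        masks = [np.ones((4, 4), bool), np.zeros((4, 4), bool)]
        heats = [np.ones((4, 4), np.float32), np.ones((4, 4), np.float32)]
        per = [localization_iou(h, m) for h, m in zip(heats, masks)]
        assert mean_iou(heats, masks) == pytest.approx(np.mean(per))
        assert 0.0 <= mean_iou(heats, masks) <= 1.0
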