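"""Network architecture: UA and MHFF oracles, shape contracts, ablation flags."""

import numpy as np
import pytest

from clickseg.clicks import Click, ClickSet
from clickseg.network import (
    ASPP,
    InteractiveSegModel,
    MultiHeadFeatureFusion,
    NetworkConfig,
    UpsamplingAttention,
    XceptionBackbone,
    build_input,
    build_model,
    predict_mask,
)
from clickseg.nn import SGD, Tensor, no_grad
from clickseg.nn import autograd as ag
from oracles import mhff_manual, ua_manual


class TestUpsamplingAttention:
    def test_zeroed_excitation_halves_low_level_map(self, rng):
        """With all FC parameters zero the weight vector is sigmoid(0) = 0.5,
        so the gated skip features are exactly half the input."""
        ua = UpsamplingAttention(ch_high=8, ch_low=4, reduction=2, rng=rng)
        for p in ua.parameters():
            p.data[...] = 0.0
        high = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
        low = Tensor(rng.standard_normal((2, 4, 12, 12)).astype(np.float32))
        out = ua(high, low)
        np.testing.assert_array_equal(out.data, 0.5 * low.data)

    def test_hand_set_weights_match_manual_evaluation(self, rng):
        """1x1-spatial high-level map, Ch=4, r=2, Cl=3, hand-set matrices."""
        ua = UpsamplingAttention(ch_high=4, ch_low=3, reduction=2, rng=rng)
        w1 = np.arange(8, dtype=np.float32).reshape(4, 2) * 0.1 - 0.3
        b1 = np.array([0.1, -0.2], dtype=np.float32)
        w2 = np.arange(6, dtype=np.float32).reshape(2, 3) * 0.2 - 0.5
        b2 = np.array([0.05, 0.0, -0.05], dtype=np.float32)
        ua.fc1.weight.data = w1
        ua.fc1.bias.data = b1
        ua.fc2.weight.data = w2
        ua.fc2.bias.data = b2
        high = rng.standard_normal((1, 4, 1, 1)).astype(np.float32)
        low = rng.standard_normal((1, 3, 2, 2)).astype(np.float32)
        out = ua(Tensor(high), Tensor(low)).data
        ref = ua_manual(high, low, w1, b1, w2, b2)
        assert np.abs(out - ref).max() < 1e-6

    def test_weight_vector_always_in_unit_interval(self, rng):
        ua = UpsamplingAttention(ch_high=6, ch_low=5, reduction=3, rng=rng)
        for _ in range(5):
            high = Tensor((rng.standard_normal((2, 6, 4, 4)) * 3).astype(np.float32))
            w = ua.weight_vector(high).data
            assert ((w > 0) & (w < 1)).all()

    def test_preserves_sign_pattern_of_low_level_map(self, rng):
        ua = UpsamplingAttention(ch_high=4, ch_low=3, reduction=2, rng=rng)
        high = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        low_data = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        out = ua(high, Tensor(low_data)).data
        assert (np.sign(out) == np.sign(low_data)).all()

    def test_channel_mismatch_raises(self, rng):
        ua = UpsamplingAttention(ch_high=4, ch_low=3, reduction=2, rng=rng)
        with pytest.raises(ValueError, match="high-level channels"):
            ua(Tensor(np.zeros((1, 5, 2, 2), np.float32)), Tensor(np.zeros((1, 3, 4, 4), np.float32)))


class TestMultiHeadFeatureFusion:
    def test_output_shape_is_2h_2w_48(self, rng):
        mhff = MultiHeadFeatureFusion(256, 144, 48, rng)
        high = Tensor(rng.standard_normal((1, 256, 8, 8)).astype(np.float32))
        low = Tensor(rng.standard_normal((1, 144, 16, 16)).astype(np.float32))
        assert mhff(high, low).shape == (1, 48, 16, 16)

    def test_all_zero_kernels_give_zero_output(self, rng):
        mhff = MultiHeadFeatureFusion(4, 3, 5, rng)
        for p in mhff.parameters():
            p.data[...] = 0.0
        high = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        low = Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32))
        assert (mhff(high, low).data == 0).all()

    def test_hand_computation_single_channel(self, rng):
        """2x2 high / 4x4 low single-channel inputs with hand-set kernels
        match a step-by-step manual execution of the fusion procedure."""
        mhff = MultiHeadFeatureFusion(1, 1, 1, rng)
        w_high = np.array([[[[0.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, 0.0]]]], np.float32)
        b_high = np.array([0.5], np.float32)
        w_low = np.array([[[[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]]]], np.float32)
        b_low = np.array([-0.25], np.float32)
        w_fuse = rng.standard_normal((1, 2, 3, 3)).astype(np.float32)
        b_fuse = np.array([0.1], np.float32)
        mhff.conv_high.weight.data = w_high
        mhff.conv_high.bias.data = b_high
        mhff.conv_low.weight.data = w_low
        mhff.conv_low.bias.data = b_low
        mhff.conv_fuse.weight.data = w_fuse
        mhff.conv_fuse.bias.data = b_fuse
        high = rng.standard_normal((1, 1, 2, 2)).astype(np.float32)
        low = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        out = mhff(Tensor(high), Tensor(low)).data
        ref = mhff_manual(high, low, w_high, b_high, w_low, b_low, w_fuse, b_fuse)
        assert out.shape == (1, 1, 4, 4)
        assert np.abs(out - ref).max() < 1e-6

    def test_distinct_kernels_for_the_two_heads(self, rng):
        mhff = MultiHeadFeatureFusion(4, 4, 8, rng)
        assert mhff.conv_high.weight is not mhff.conv_low.weight
        assert not np.array_equal(mhff.conv_high.weight.data, mhff.conv_low.weight.data)

    def test_spatial_mismatch_raises(self, rng):
        mhff = MultiHeadFeatureFusion(2, 2, 4, rng)
        with pytest.raises(ValueError, match="2x"):
            mhff(
                Tensor(np.zeros((1, 2, 4, 4), np.float32)),
                Tensor(np.zeros((1, 2, 16, 16), np.float32)),
            )


class TestASPP:
    def test_preserves_spatial_size(self, rng):
        aspp = ASPP(16, 8, (1, 6, 12, 18), rng)
        aspp.eval()
        x = Tensor(rng.standard_normal((1, 16, 32, 32)).astype(np.float32))
        with no_grad():
            assert aspp(x).shape == (1, 8, 32, 32)

    def test_constant_input_gives_constant_pooling_branch(self, rng):
        """The image-level branch of a constant map is spatially constant and
        equals the 1x1 projection of that constant."""
        from clickseg.network import _reshape4

        aspp = ASPP(3, 4, (1, 6, 12, 18), rng)
        aspp.eval()
        x = Tensor(np.full((1, 3, 16, 16), 2.0, np.float32))
        with no_grad():
            pooled = ag.global_avg_pool(x)
            assert np.allclose(pooled.data, 2.0)
            branch = aspp.pool_conv(_reshape4(pooled))
            y = ag.resize_bilinear(branch, 16, 16).data
        assert np.abs(y - y[:, :, :1, :1]).max() < 1e-6
        w = aspp.pool_conv.conv.weight.data  # (4, 3, 1, 1)
        raw = (w[:, :, 0, 0] * 2.0).sum(axis=1)
        expected = np.maximum(raw / np.sqrt(1.0 + aspp.pool_conv.bn.eps), 0.0)
        np.testing.assert_allclose(y[0, :, 0, 0], expected, atol=1e-5)

    def test_rate_one_branch_matches_direct_convolution(self, rng):
        """Impulse input through the rate-1 branch equals the direct
        convolution, up to the (eval-mode, default-stats) batch-norm scale."""
        aspp = ASPP(1, 1, (1,), rng)
        aspp.eval()
        x = np.zeros((1, 1, 5, 5), np.float32)
        x[0, 0, 2, 2] = 1.0
        branch = aspp.branch0
        with no_grad():
            y = branch(Tensor(x)).data
        from oracles import conv2d_direct

        raw = conv2d_direct(x, branch.conv.weight.data, None, pad=1)
        ref = np.maximum(raw / np.sqrt(1.0 + branch.bn.eps), 0.0)
        assert np.abs(y - ref).max() < 1e-6


class TestModelContracts:
    def test_backbone_channel_contract_at_stride_2_4_8(self, rng):
        cfg = NetworkConfig(backbone="simple")
        m = build_model(cfg, seed=0).eval()
        x = Tensor(np.zeros((1, 5, 64, 64), np.float32))
        with no_grad():
            pyr = m.backbone_forward(x)
        assert pyr["f2"].shape == (1, 128, 32, 32)
        assert pyr["f4"].shape == (1, 256, 16, 16)
        assert pyr["f8"].shape == (1, 728, 8, 8)
        assert pyr["f16"].shape == (1, 2048, 4, 4)

    def test_xception_backbone_same_contract(self, rng):
        cfg = NetworkConfig(backbone="xception", middle_blocks=2)
        m = XceptionBackbone(cfg, rng).eval()
        with no_grad():
            pyr = m(Tensor(np.zeros((1, 5, 64, 64), np.float32)))
        assert pyr["f2"].shape == (1, 128, 32, 32)
        assert pyr["f4"].shape == (1, 256, 16, 16)
        assert pyr["f8"].shape == (1, 728, 8, 8)
        assert pyr["f16"].shape == (1, 2048, 4, 4)

    def test_skip_reduction_channels(self):
        m = build_model(NetworkConfig(backbone="simple"), seed=0).eval()
        with no_grad():
            pyr = m.backbone_forward(Tensor(np.zeros((1, 5, 64, 64), np.float32)))
            red = m.reduce_skips(pyr)
        assert red["f2"].shape[1] == 24
        assert red["f4"].shape[1] == 48
        assert red["f8"].shape[1] == 144

    def test_non_divisible_input_names_offending_dimension(self):
        m = build_model(NetworkConfig.test_size(), seed=0)
        with pytest.raises(ValueError, match="height 60"):
            m.backbone_forward(Tensor(np.zeros((1, 5, 60, 64), np.float32)))
        with pytest.raises(ValueError, match="width 50"):
            m.backbone_forward(Tensor(np.zeros((1, 5, 64, 50), np.float32)))

    @pytest.mark.parametrize("use_mhff,use_ua", [(False, False), (True, False), (False, True), (True, True)])
    def test_all_ablation_configs_run_end_to_end(self, use_mhff, use_ua):
        cfg = NetworkConfig.test_size(use_mhff=use_mhff, use_ua=use_ua)
        m = build_model(cfg, seed=1).eval()
        x = Tensor(np.random.default_rng(0).standard_normal((1, 5, 64, 64)).astype(np.float32))
        with no_grad():
            logits = m(x)
        assert logits.shape == (1, 2, 64, 64)
        assert np.isfinite(logits.data).all()

    def test_width_multiplier_preserves_stride_structure(self):
        cfg = NetworkConfig.test_size(width_multiplier=0.0625)
        m = build_model(cfg, seed=0).eval()
        with no_grad():
            pyr = m.backbone_forward(Tensor(np.zeros((1, 5, 32, 32), np.float32)))
        assert pyr["f2"].shape[2:] == (16, 16)
        assert pyr["f4"].shape[2:] == (8, 8)
        assert pyr["f8"].shape[2:] == (4, 4)
        assert pyr["f16"].shape[2:] == (2, 2)

    def test_zeroed_ua_equals_halved_low_level_input(self, rng):
        """In a fusion stage with zeroed UA parameters the skip features
        entering the fusion are exactly halved."""
        from clickseg.network import _FusionStage

        cfg = NetworkConfig.test_size(use_mhff=True, use_ua=True)
        stage = _FusionStage(8, 4, 6, cfg, np.random.default_rng(0))
        stage.eval()
        for p in stage.ua.parameters():
            p.data[...] = 0.0
        high = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        low = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        with no_grad():
            out_ua = stage(high, Tensor(low))
            out_halved = ag.relu(stage.mhff(high, Tensor(0.5 * low)))
        np.testing.assert_allclose(out_ua.data, out_halved.data, atol=1e-6)

    def test_all_zero_input_produces_finite_outputs(self):
        m = build_model(NetworkConfig.test_size(), seed=0).eval()
        with no_grad():
            logits = m(Tensor(np.zeros((1, 5, 32, 32), np.float32)))
        assert np.isfinite(logits.data).all()

    def test_one_sgd_step_updates_mhff_and_ua_parameters(self, overfit_set):
        """Gradient flow: no dead decoder modules after a single step."""
        cfg = NetworkConfig.test_size()
        m = build_model(cfg, seed=2)
        m.train()
        image, mask = overfit_set[0]
        from clickseg.clicks import centered_click
        from clickseg.network import build_input

        x = Tensor(build_input(image, centered_click(mask))[None])
        target = mask.astype(np.int64)[None]
        logits = m(x)
        loss = ag.softmax_cross_entropy(logits, target)
        before = {
            name: p.data.copy()
            for name, p in m.named_parameters()
            if "mhff" in name or "ua" in name
        }
        assert before, "decoder should expose MHFF and UA parameters"
        opt = SGD(m.parameters(), lr=0.05)
        opt.zero_grad()
        loss.backward()
        opt.step()
        changed = [
            name for name, p in m.named_parameters()
            if name in before and not np.array_equal(before[name], p.data)
        ]
        assert any("mhff" in n for n in changed)
        assert any("ua" in n for n in changed)


class TestPredictMask:
    def test_shapes_and_probability_normalisation(self, overfit_set):
        m = build_model(NetworkConfig.test_size(), seed=0)
        image, mask = overfit_set[0]
        from clickseg.clicks import centered_click

        pred, prob = predict_mask(m, image, centered_click(mask))
        assert pred.shape == image.shape[:2]
        assert prob.shape == image.shape[:2]
        assert ((prob >= 0) & (prob <= 1)).all()

    def test_non_multiple_of_16_image_is_padded_and_cropped_back(self):
        class StubModel:
            """Logits +1 on a fixed square, -1 elsewhere (channel 1)."""

            config = NetworkConfig.test_size()

            def eval(self):
                return self

            def __call__(self, x):
                n, _, h, w = x.shape
                logits = np.zeros((n, 2, h, w), np.float32)
                logits[:, 1] = -1.0
                logits[:, 1, 10:30, 5:25] = 1.0
                logits[:, 0] = 0.0
                return Tensor(logits)

        image = np.zeros((70, 90, 3), np.uint8)
        clicks = ClickSet()
        clicks.add(Click(12, 12, "positive"))
        mask, prob = predict_mask(StubModel(), image, clicks)
        assert mask.shape == (70, 90)
        expected = np.zeros((70, 90), np.uint8)
        expected[10:30, 5:25] = 1
        np.testing.assert_array_equal(mask, expected)

    def test_five_channel_input_stacking(self, overfit_set):
        image, mask = overfit_set[0]
        from clickseg.clicks import centered_click

        x = build_input(image, centered_click(mask))
        assert x.shape == (5, 64, 64)
        np.testing.assert_array_equal(x[:3], image.transpose(2, 0, 1))
        click = centered_click(mask).positives[0]
        assert x[3, click.row, click.col] == 0.0  # positive map zero at click
        assert (x[4] == 255.0).all()  # no negative clicks

    def test_inference_is_deterministic(self, overfit_set):
        m = build_model(NetworkConfig.test_size(), seed=0)
        image, mask = overfit_set[1]
        from clickseg.clicks import centered_click

        a, pa = predict_mask(m, image, centered_click(mask))
        b, pb = predict_mask(m, image, centered_click(mask))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(pa, pb)
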