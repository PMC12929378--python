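"""Behavioural contracts of the architecture blocks: shuffle permutation,
reparameterization equivalence, attention identities, downsampling shapes
and the analytic 3.6× cost ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldseg.blocks import (
    ADown,
    IRMB,
    RCSOSA,
    RepConv,
    SEAM,
    channel_shuffle,
    downsample_cost,
    shuffle_permutation,
)
from fieldseg.nn import Tensor, flop_counter


def _rand(shape, seed=0, dtype=np.float64):
    return Tensor(np.random.default_rng(seed).normal(size=shape).astype(dtype))


def _randomize_bn_stats(module, seed=0):
    """Give every BatchNorm non-trivial running statistics (as training would)."""
    rng = np.random.default_rng(seed)
    for name, buf in module.named_buffers():
        if name.endswith("running_mean"):
            buf[...] = rng.normal(0, 0.5, buf.shape)
        elif name.endswith("running_var"):
            buf[...] = rng.uniform(0.5, 2.0, buf.shape)


class TestChannelShuffle:
    def test_groups_one_is_identity(self):
        x = _rand((2, 6, 4, 4))
        assert np.array_equal(channel_shuffle(x, 1).data, x.data)

    def test_c4_g2_permutation(self):
        # reshape (2,2) -> transpose -> flatten maps (0,1,2,3) to (0,2,1,3)
        x = Tensor(np.arange(4, dtype=float).reshape(1, 4, 1, 1))
        y = channel_shuffle(x, 2)
        assert y.data.ravel().tolist() == [0.0, 2.0, 1.0, 3.0]

    @given(st.sampled_from([(4, 2), (8, 2), (8, 4), (12, 3), (16, 4)]))
    @settings(max_examples=20, deadline=None)
    def test_bijection_and_conservation(self, cg):
        c, g = cg
        x = _rand((1, c, 3, 3), seed=c * g)
        y = channel_shuffle(x, g)
        p = shuffle_permutation(c, g)
        assert np.array_equal(y.data, x.data[:, p])
        inv = np.argsort(p)
        assert np.array_equal(y.data[:, inv], x.data)  # inverse restores bit-exactly
        np.testing.assert_allclose(
            sorted(y.data.sum(axis=(0, 2, 3))), sorted(x.data.sum(axis=(0, 2, 3)))
        )

    def test_non_divisible_raises(self):
        with pytest.raises(ValueError):
            channel_shuffle(_rand((1, 6, 2, 2)), 4)


class TestRepConv:
    def test_identity_branch_only_unit_normalization(self):
        rc = RepConv(4, 4, rng=np.random.default_rng(0), dtype=np.float64)
        rc.conv3.weight.data[...] = 0.0
        rc.conv1.weight.data[...] = 0.0
        rc.bnid.running_var[...] = 1.0 - rc.bnid.eps  # unit 1/sqrt(var+eps)
        rc.eval()
        x = _rand((2, 4, 5, 5))
        np.testing.assert_allclose(rc(x).data, x.data, atol=1e-12)

    def test_zeroed_1x1_branch_changes_nothing(self):
        rc = RepConv(4, 4, rng=np.random.default_rng(1), dtype=np.float64)
        _randomize_bn_stats(rc, 1)
        rc.eval()
        x = _rand((1, 4, 6, 6), seed=2)
        full = rc(x).data
        with_1x1_zeroed = None
        w1 = rc.conv1.weight.data.copy()
        rc.conv1.weight.data[...] = 0.0
        rc.bn1.beta.data[...] = 0.0
        rc.bn1.running_mean[...] = 0.0
        with_1x1_zeroed = rc(x).data
        rc.conv1.weight.data[...] = w1
        # reference: 3x3 + identity branches summed by hand
        from fieldseg.nn import conv2d

        ref = rc.bn3(rc.conv3(x)) + rc.bnid(x)
        np.testing.assert_allclose(with_1x1_zeroed, ref.data, atol=1e-12)

    def test_fuse_equivalence_many_random_inputs(self):
        rc = RepConv(6, 6, rng=np.random.default_rng(3), dtype=np.float64)
        _randomize_bn_stats(rc, 3)
        rc.eval()
        xs = [_rand((1, 6, 7, 7), seed=s) for s in range(50)]
        branched = [rc(x).data for x in xs]
        rc.fuse()
        for x, ref in zip(xs, branched):
            assert np.abs(rc(x).data - ref).max() < 1e-4

    def test_fuse_idempotent(self):
        rc = RepConv(4, 4, rng=np.random.default_rng(4))
        _randomize_bn_stats(rc, 4)
        rc.fuse()
        w1, b1 = rc.fused_weight.copy(), rc.fused_bias.copy()
        rc.fuse()
        np.testing.assert_array_equal(w1, rc.fused_weight)
        np.testing.assert_array_equal(b1, rc.fused_bias)

    def test_deploy_without_fuse_raises(self):
        rc = RepConv(4, 4)
        rc.deploy = True
        with pytest.raises(RuntimeError):
            rc(_rand((1, 4, 5, 5)))


class TestRCSOSA:
    @pytest.mark.parametrize("n_repeats,out_ch", [(1, 8), (2, 16), (3, 8)])
    def test_shape_contract(self, n_repeats, out_ch):
        blk = RCSOSA(8, out_ch, n_repeats=n_repeats, rng=np.random.default_rng(0))
        y = blk(_rand((2, 8, 9, 9), dtype=np.float32))
        assert y.shape == (2, out_ch, 9, 9)

    def test_deploy_equals_train_after_fuse(self):
        blk = RCSOSA(8, 12, n_repeats=2, rng=np.random.default_rng(1), dtype=np.float64)
        _randomize_bn_stats(blk, 1)
        blk.eval()
        x = _rand((1, 8, 10, 10), seed=9)
        ref = blk(x).data
        for u in blk.units:
            u.rep.fuse()
        assert np.abs(blk(x).data - ref).max() < 1e-4

    def test_untransformed_half_survives_up_to_shuffle(self):
        blk = RCSOSA(4, 4, n_repeats=1, rng=np.random.default_rng(2), dtype=np.float64)
        u = blk.units[0]
        u.rep.conv3.weight.data[...] = 0.0
        u.rep.conv1.weight.data[...] = 0.0
        u.eval()
        x = _rand((1, 4, 5, 5), seed=3)
        y = u(x)  # the raw unit output, before the 1x1 projection
        p = shuffle_permutation(4, u.groups)
        unshuffled = y.data[:, np.argsort(p)]
        np.testing.assert_allclose(unshuffled[:, :2], x.data[:, :2], atol=1e-12)

    def test_odd_channels_raise(self):
        with pytest.raises(ValueError):
            RCSOSA(5, 8)


class TestSEAM:
    def test_output_shape_equals_input(self):
        s = SEAM(8, rng=np.random.default_rng(0))
        x = _rand((2, 8, 7, 7), dtype=np.float32)
        assert s(x).shape == x.shape

    def test_zero_fc_gives_residual_path_value(self):
        s = SEAM(8, rng=np.random.default_rng(1), dtype=np.float64)
        s.fc1.weight.data[...] = 0.0
        s.fc1.bias.data[...] = 0.0
        s.fc2.weight.data[...] = 0.0
        s.fc2.bias.data[...] = 0.0
        s.eval()
        x = _rand((1, 8, 6, 6), seed=5)
        residual = (s.pw(s.dw(x)) + x).data
        np.testing.assert_allclose(s(x).data, residual, atol=1e-12)

    @pytest.mark.parametrize("gate", ["exp", "sigmoid"])
    def test_channel_weights_strictly_positive(self, gate):
        s = SEAM(8, gate=gate, rng=np.random.default_rng(2), dtype=np.float64)
        s.eval()
        x = _rand((1, 8, 6, 6), seed=6)
        pooled = (s.pw(s.dw(x)) + x).mean(axis=(2, 3))
        z = s.fc2(s.fc1(pooled).relu()).clip(-4.0, 4.0)
        w = z.exp() if gate == "exp" else z.sigmoid()
        assert (w.data > 0).all()

    def test_unknown_gate_raises(self):
        with pytest.raises(ValueError):
            SEAM(8, gate="tanh")


class TestIRMB:
    def test_zero_projection_residual_identity(self):
        blk = IRMB(8, 8, stride=1, rng=np.random.default_rng(0), dtype=np.float64)
        blk.proj.conv.weight.data[...] = 0.0
        blk.proj.bn.beta.data[...] = 0.0
        blk.proj.bn.running_mean[...] = 0.0
        blk.eval()
        x = _rand((1, 8, 7, 7), seed=1)
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-12)

    def test_single_token_attention_is_value_projection(self):
        # with one spatial token the softmax over keys is trivially 1, so
        # attention returns exactly the value path
        from fieldseg.blocks import _WindowAttention

        attn = _WindowAttention(8, 2, 7, np.random.default_rng(2), np.float64)
        x = _rand((1, 8, 1, 1), seed=2)
        qkv = attn.qkv(x).data.reshape(3, 8)
        np.testing.assert_allclose(attn(x).data.ravel(), qkv[2], atol=1e-10)

    @pytest.mark.parametrize("stride,out_ch", [(1, 12), (2, 8)])
    def test_shape_contract(self, stride, out_ch):
        blk = IRMB(8, out_ch, stride=stride, rng=np.random.default_rng(3))
        y = blk(_rand((2, 8, 14, 14), dtype=np.float32))
        assert y.shape == (2, out_ch, 14 // stride, 14 // stride)

    def test_pad_and_crop_for_non_divisible_window(self):
        blk = IRMB(8, 8, window=7, rng=np.random.default_rng(4))
        y = blk(_rand((1, 8, 10, 10), dtype=np.float32))  # 10 % 7 != 0
        assert y.shape == (1, 8, 10, 10)
        assert np.isfinite(y.data).all()


class TestADown:
    def test_shape_contract_full_resolution(self):
        blk = ADown(64, 128, rng=np.random.default_rng(0))
        y = blk(Tensor(np.zeros((1, 64, 480, 480), np.float32)))
        assert y.shape == (1, 128, 240, 240)

    def test_output_channels_sum_of_halves(self):
        blk = ADown(8, 20, rng=np.random.default_rng(1))
        y = blk(_rand((1, 8, 16, 16), dtype=np.float32))
        assert y.shape[1] == blk.cv_conv.conv.out_ch + blk.cv_pool.conv.out_ch == 20

    def test_constant_input_conv_branch_interior(self):
        blk = ADown(4, 4, rng=np.random.default_rng(2), dtype=np.float64)
        blk.eval()
        const = 1.7
        x = Tensor(np.full((1, 4, 12, 12), const))
        y = blk(x)
        # hand evaluation: avg-pool of a constant is the constant; interior
        # outputs of the 3x3 conv branch are bn(const * kernel_sum)
        ksum = blk.cv_conv.conv.weight.data.sum(axis=(1, 2, 3))
        bn = blk.cv_conv.bn
        pre = const * ksum
        ref = (pre - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
        ref = ref * bn.gamma.data + bn.beta.data
        ref = ref / (1 + np.exp(-ref))  # SiLU
        got = y.data[0, :2, 2:-2, 2:-2]  # conv half, interior pixels
        for c in range(2):
            np.testing.assert_allclose(got[c], ref[c], atol=1e-10)

    def test_odd_channels_raise(self):
        with pytest.raises(ValueError):
            ADown(5, 8)

    def test_tiny_spatial_raises(self):
        blk = ADown(4, 4)
        with pytest.raises(ValueError):
            blk(Tensor(np.zeros((1, 4, 1, 1), np.float32)))


class TestDownsampleCost:
    @pytest.mark.parametrize("c", [2, 8, 64, 256])
    def test_ratios_exactly_18_over_5(self, c):
        r = downsample_cost(c, 32, 32)
        assert r.ratio_params == 3.6 == 18 / 5
        assert r.ratio_flops == 3.6

    def test_conv_params_are_9c2(self):
        for c in (4, 16, 128):
            assert downsample_cost(c, 8, 8).params_conv == 9 * c * c

    def test_adown_flops_match_mac_enumeration(self):
        # oracle: count the multiply-accumulates actually executed by the
        # ADown module's convolutions on a c=8, 16x16 input
        c, h, w = 8, 16, 16
        blk = ADown(c, c, rng=np.random.default_rng(0))
        blk.eval()
        with flop_counter() as fc:
            blk(Tensor(np.zeros((1, c, h, w), np.float32)))
        assert fc.macs == downsample_cost(c, h, w).flops_adown == (5 / 8) * c * c * h * w

    def test_conv_flops_match_mac_enumeration(self):
        from fieldseg.nn import ConvBnAct

        c, h, w = 8, 16, 16
        conv = ConvBnAct(c, c, 3, stride=2, rng=np.random.default_rng(0))
        conv.eval()
        with flop_counter() as fc:
            conv(Tensor(np.zeros((1, c, h, w), np.float32)))
        assert fc.macs == downsample_cost(c, h, w).flops_conv

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            downsample_cost(3, 8, 8)
        with pytest.raises(ValueError):
            downsample_cost(4, 0, 8)
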