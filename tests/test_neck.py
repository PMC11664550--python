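"""Neck blocks: DySample vs a naive bilinear oracle, reparameterization
equivalence, pooling/concat contracts, attention and dual-stream fusion."""

import numpy as np
import pytest

import sgsnet as sg
from sgsnet._tensor import Tensor, concatenate
from sgsnet.neck import (AConv, DySample, IRMB, RepConv, RepNCSPELAN4,
                         SPPELAN, DualStreamFusion, fuse_streams)


def naive_bilinear(x, coords):
    """Per-pixel bilinear resampler with border clamping (oracle)."""
    n, c, h, w = x.shape
    ho, wo = coords.shape[1:3]
    out = np.zeros((n, c, ho, wo), x.dtype)
    for ni in range(n):
        for i in range(ho):
            for j in range(wo):
                cx = min(max(coords[ni, i, j, 0], 0.0), w - 1.0)
                cy = min(max(coords[ni, i, j, 1], 0.0), h - 1.0)
                x0, y0 = int(np.floor(cx)), int(np.floor(cy))
                x0, y0 = min(x0, w - 2), min(y0, h - 2)
                fx, fy = cx - x0, cy - y0
                for ci in range(c):
                    v = (x[ni, ci, y0, x0] * (1 - fy) * (1 - fx)
                         + x[ni, ci, y0, x0 + 1] * (1 - fy) * fx
                         + x[ni, ci, y0 + 1, x0] * fy * (1 - fx)
                         + x[ni, ci, y0 + 1, x0 + 1] * fy * fx)
                    out[ni, ci, i, j] = v
    return out


class TestDySample:
    def _zeroed(self, channels=8, seed=0):
        ds = DySample(channels, np.random.default_rng(seed))
        ds.offset_conv.weight.data[:] = 0.0
        ds.offset_conv.bias.data[:] = 0.0
        return ds

    def test_zero_offsets_equal_plain_bilinear(self, rng):
        ds = self._zeroed()
        x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        got = ds(Tensor(x)).data
        want = naive_bilinear(x, ds.base_grid(6, 6)[None].repeat(2, axis=0))
        assert got.shape == (2, 8, 12, 12)
        assert np.allclose(got, want, atol=1e-6)

    def test_constant_one_pixel_offset_shifts_interior(self, rng):
        ds = self._zeroed()
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        base = ds(Tensor(x)).data
        # +1 input pixel in x for every group: bias channels [gi, 0, :, :]
        b = ds.offset_conv.bias.data.reshape(ds.groups, 2, 4)
        b[:, 0, :] = 1.0 / ds.offset_range
        shifted = ds(Tensor(x)).data
        # interior: shifted output at column j equals base at column j + scale
        assert np.allclose(shifted[..., 2:-4], base[..., 4:-2], atol=1e-5)

    def test_constant_input_invariant_to_offsets(self):
        ds = DySample(4, np.random.default_rng(3))
        ds.offset_conv.bias.data[:] = np.linspace(-2, 2, ds.offset_conv.bias.size)
        x = np.full((1, 4, 5, 5), 3.25, np.float32)
        assert np.allclose(ds(Tensor(x)).data, 3.25, atol=1e-6)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            DySample(8, np.random.default_rng(0), scale=1)


class TestReparameterization:
    def test_single_branch_modes_identical(self, rng):
        rc = RepConv(3, 4, (3,), np.random.default_rng(1))
        x = Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32))
        train = rc(x).data
        rc.set_deploy(True)
        assert np.allclose(train, rc(x).data, atol=1e-6)

    def test_multi_branch_equivalence_100_seeds(self):
        worst = 0.0
        for seed in range(100):
            g = np.random.default_rng(seed)
            rc = RepConv(4, 6, (3, 3, 1), g)
            x = Tensor(g.standard_normal((1, 4, 8, 8)).astype(np.float32))
            train = rc(x).data
            rc.set_deploy(True)
            worst = max(worst, float(np.abs(train - rc(x).data).max()))
        assert worst < 1e-5

    def test_zero_weight_branches_give_zero(self, rng):
        rc = RepConv(3, 2, (3, 1), np.random.default_rng(0))
        for br in rc.branches:
            br.weight.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 3, 5, 5)).astype(np.float32))
        assert np.allclose(rc(x).data, 0.0)

    def test_elan_block_train_deploy_agree(self, rng):
        blk = RepNCSPELAN4(8, 8, 4, np.random.default_rng(2))
        blk.set_training(False)
        x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        train = blk(x).data
        blk.set_deploy(True)
        assert np.allclose(train, blk(x).data, atol=1e-5)


class TestPoolingConcat:
    def test_concat_stacks_channels(self, rng):
        a = Tensor(rng.standard_normal((1, 4, 6, 6)))
        b = Tensor(rng.standard_normal((1, 6, 6, 6)))
        assert concatenate([a, b], axis=1).shape == (1, 10, 6, 6)

    def test_sppelan_constant_map_stays_constant(self):
        sp = SPPELAN(4, 6, 4, np.random.default_rng(0))
        sp.set_training(False)
        x = Tensor(np.full((1, 4, 8, 8), 2.0, np.float32))
        y = sp(x).data
        assert np.allclose(y, y[..., :1, :1], atol=1e-5)

    def test_sppelan_output_channels(self, rng):
        sp = SPPELAN(8, 12, 4, np.random.default_rng(1))
        sp.set_training(False)
        y = sp(Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32)))
        assert y.shape == (2, 12, 8, 8)

    def test_aconv_downsamples(self, rng):
        ac = AConv(4, 6, np.random.default_rng(0))
        ac.set_training(False)
        y = ac(Tensor(rng.standard_normal((1, 4, 10, 10)).astype(np.float32)))
        assert y.shape == (1, 6, 5, 5)


class TestIRMB:
    def test_shape_preserved(self, rng):
        ir = IRMB(8, np.random.default_rng(0), heads=2, window=4)
        ir.set_training(False)
        x = Tensor(rng.standard_normal((2, 8, 9, 9)).astype(np.float32))
        assert ir(x).shape == (2, 8, 9, 9)

    def test_heads_must_divide_channels(self):
        with pytest.raises(ValueError):
            IRMB(6, np.random.default_rng(0), heads=4)

    def test_attention_rows_sum_to_one(self, rng):
        # softmax normalization observed through a constant-value probe:
        # with V ≡ 1 the attention output must be exactly 1 per query
        ir = IRMB(4, np.random.default_rng(1), heads=2, window=3)
        x = Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32))
        ir.v.weight.data[:] = 0.0
        ir.v.bias = None
        ones = ir.attention(x)
        # V(x) = 0 -> attention output 0 regardless of weights
        assert np.allclose(ones.data, 0.0, atol=1e-6)
        # direct check on the normalized weights via the value-of-ones trick
        ir.v.weight.data[:] = 0.0
        from sgsnet.layers import ConvSpec, Conv2dLayer
        ir.v = Conv2dLayer(ConvSpec(1, 1, 4, 4, 1, True), np.random.default_rng(0))
        ir.v.weight.data[:] = 0.0
        ir.v.bias.data[:] = 1.0
        out = ir.attention(x)
        assert np.allclose(out.data, 1.0, atol=1e-6)

    def test_degenerate_window_identity(self, rng):
        # 1x1 windows, identity value projection, delta depthwise kernel:
        # the block reduces to x + proj(x)
        ir = IRMB(3, np.random.default_rng(2), heads=1, window=1)
        ir.set_training(False)
        ir.v.weight.data[:] = np.eye(3, dtype=np.float32).reshape(3, 3, 1, 1)
        ir.dw.conv.weight.data[:] = 0.0
        ir.dw.conv.weight.data[:, 0, 1, 1] = 1.0
        ir.proj.conv.weight.data[:] = np.eye(3, dtype=np.float32).reshape(3, 3, 1, 1)
        x = Tensor(rng.random((1, 3, 4, 4), dtype=np.float32) + 0.5)
        got = ir(x).data
        want = x.data + np.maximum(x.data, 0.0)  # dw BN-ReLU on positives
        assert np.allclose(got, want, atol=1e-4)


class TestDualStreamFusion:
    def test_zero_weights_give_constant_two(self, rng):
        a = Tensor(rng.standard_normal((1, 4, 5, 5)))
        b = Tensor(rng.standard_normal((1, 4, 5, 5)))
        assert np.allclose(fuse_streams(a, b, 0.0, 0.0).data, 2.0)

    def test_unit_lambda_recovers_stream_plus_two(self, rng):
        a = Tensor(rng.standard_normal((1, 4, 5, 5)))
        b = Tensor(rng.standard_normal((1, 4, 5, 5)))
        assert np.allclose(fuse_streams(a, b, 1.0, 0.0).data, a.data + 2.0,
                           atol=1e-6)

    def test_gradient_wrt_lambda_equals_stream(self):
        g = np.random.default_rng(42)
        a = g.standard_normal((1, 4, 5, 5))
        b = g.standard_normal((1, 4, 5, 5))
        lam = Tensor(np.zeros_like(a), requires_grad=True)
        out = fuse_streams(Tensor(a), Tensor(b), lam, 0.5)
        out.sum().backward()
        assert np.allclose(lam.grad, a, atol=1e-6)
        # finite-difference cross-check at a single element
        eps = 1e-3
        lam2 = np.zeros_like(a)
        lam2[0, 1, 2, 3] = eps
        diff = (fuse_streams(Tensor(a), Tensor(b), Tensor(lam2), 0.5).data.sum()
                - fuse_streams(Tensor(a), Tensor(b), Tensor(np.zeros_like(a)), 0.5).data.sum())
        assert abs(diff / eps - a[0, 1, 2, 3]) < 1e-2

    def test_block_output_shape_and_refinement_path(self, rng):
        blk = DualStreamFusion(8, 8, 4, np.random.default_rng(0), heads=2,
                               window=3)
        blk.set_training(False)
        x = Tensor(rng.standard_normal((1, 8, 6, 6)).astype(np.float32))
        assert blk(x).shape == (1, 8, 6, 6)
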