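"""The detector neck: reparameterizable aggregation, adaptive upsampling and
dual-stream attention fusion.

Three fusion paths connect the backbone pyramid to the heads.  The deepest
level passes through spatial-pyramid pooling (SPPELAN); its output is
upsampled by DySample (bilinear resampling at a regular grid perturbed by
learned per-pixel offsets), concatenated with the lateral level and fused by
a dual-stream block: a reparameterizable multi-branch aggregation stream
(RepNCSPELAN4) and a windowed-attention mobile block stream (iRMB), combined
by trainable per-channel weights.  Downsampling returns through strided
AConv blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from numpy.lib.stride_tricks import sliding_window_view

from ._tensor import (Tensor, concatenate, conv2d, grid_sample_bilinear,
                      max_pool2d, unfold)
from .layers import BatchNorm2d, Conv2dLayer, ConvBNReLU, ConvSpec, Module

__all__ = ["RepConv", "RepNCSPELAN4", "AConv", "SPPELAN", "DySample",
           "IRMB", "DualStreamFusion", "fuse_streams", "Neck", "NeckConfig"]


# ---------------------------------------------------------------------------
# Reparameterizable convolution and the aggregation block built on it
# ---------------------------------------------------------------------------

class RepConv(Module):
    """Multi-branch convolution that merges into a single kernel at deploy.

    Training mode evaluates the sum of the branch convolutions (kernel sizes
    ``branch_kernels``, all zero-padded to the largest); deploy mode runs one
    convolution with the merged kernel.  Both modes agree to float precision
    because the map is linear in the input.
    """

    def __init__(self, c_in: int, c_out: int, branch_kernels: tuple[int, ...],
                 rng: np.random.Generator, stride: int = 1, name: str = "rep"):
        if not branch_kernels:
            raise ValueError("need at least one branch")
        kmax = max(branch_kernels)
        if any(k % 2 == 0 or k > kmax for k in branch_kernels):
            raise ValueError("branch kernels must be odd and <= the largest")
        self.kmax = kmax
        self.stride = stride
        self.name = name
        self.branches = [
            Conv2dLayer(ConvSpec(k, k, c_in, c_out, stride, False), rng,
                        name=f"{name}.br{k}x{k}_{i}")
            for i, k in enumerate(branch_kernels)]
        self.deploy = False
        self._merged: Tensor | None = None

    def merged_kernel(self) -> np.ndarray:
        km = self.kmax
        w = np.zeros_like(self.branches[0].weight.data,
                          shape=self.branches[0].weight.shape[:2] + (km, km))
        for br in self.branches:
            k = br.spec.k_h
            off = (km - k) // 2
            w[:, :, off:off + k, off:off + k] += br.weight.data
        return w

    def set_deploy(self, mode: bool = True):
        if mode:
            self._merged = Tensor(self.merged_kernel())
        self.deploy = mode
        return self

    def forward(self, x: Tensor) -> Tensor:
        if self.deploy:
            return conv2d(x, self._merged, stride=self.stride,
                          padding=self.kmax // 2)
        # each branch at its own "same" padding: outputs align, and the sum
        # equals the merged-kernel convolution at kmax//2 padding
        y = None
        for br in self.branches:
            z = conv2d(x, br.weight, stride=self.stride, padding=br.spec.k_h // 2)
            y = z if y is None else y + z
        return y

    def audit_records(self, h: int, w: int):
        recs = []
        for br in self.branches:
            r, ho, wo = br.audit_records(h, w)
            recs += r
        return recs, ho, wo


class RepConvBNReLU(Module):
    def __init__(self, c_in, c_out, branch_kernels, rng, name="repcbr"):
        self.rep = RepConv(c_in, c_out, branch_kernels, rng, name=f"{name}.rep")
        self.bn = BatchNorm2d(c_out, name=f"{name}.bn")

    def forward(self, x):
        return self.bn(self.rep(x)).relu()

    def audit_records(self, h, w):
        recs, h, w = self.rep.audit_records(h, w)
        r, h, w = self.bn.audit_records(h, w)
        return recs + r, h, w


class RepNCSPELAN4(Module):
    """Split–transform–aggregate block with reparameterizable branches.

    A 1x1 convolution widens the input to two hidden halves; the second half
    is chained through two reparameterizable 3x3/1x1 stages; the halves and
    both stage outputs are concatenated and fused by a final 1x1 convolution.
    """

    def __init__(self, c_in: int, c_out: int, hidden: int,
                 rng: np.random.Generator, branch_kernels=(3, 1),
                 name: str = "elan"):
        self.hidden = hidden
        self.cv1 = ConvBNReLU(c_in, 2 * hidden, 1, 1, rng, name=f"{name}.cv1")
        self.stage1 = RepConvBNReLU(hidden, hidden, branch_kernels, rng,
                                    name=f"{name}.stage1")
        self.stage2 = RepConvBNReLU(hidden, hidden, branch_kernels, rng,
                                    name=f"{name}.stage2")
        self.cv4 = ConvBNReLU(4 * hidden, c_out, 1, 1, rng, name=f"{name}.cv4")

    def set_deploy(self, mode: bool = True):
        self.stage1.rep.set_deploy(mode)
        self.stage2.rep.set_deploy(mode)
        return self

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        h = self.hidden
        a, b = y[:, :h], y[:, h:]
        c = self.stage1(b)
        d = self.stage2(c)
        return self.cv4(concatenate([a, b, c, d], axis=1))

    def audit_records(self, h, w):
        recs, h1, w1 = self.cv1.audit_records(h, w)
        for sub in (self.stage1, self.stage2, self.cv4):
            r, h1, w1 = sub.audit_records(h1, w1)
            recs += r
        return recs, h1, w1


class AConv(Module):
    """Strided 3x3 convolution + activation used on the downsampling return."""

    def __init__(self, c_in: int, c_out: int, rng, name="aconv"):
        self.cbr = ConvBNReLU(c_in, c_out, 3, 2, rng, name=f"{name}")

    def forward(self, x):
        return self.cbr(x)

    def audit_records(self, h, w):
        return self.cbr.audit_records(h, w)


class SPPELAN(Module):
    """Spatial pyramid pooling: three sequential 5x5 max-pools, concatenated
    with the pre-pool features and fused by a pointwise convolution."""

    def __init__(self, c_in: int, c_out: int, hidden: int, rng,
                 pool_sizes=(5, 5, 5), name="sppelan"):
        self.pool_sizes = tuple(pool_sizes)
        self.cv1 = ConvBNReLU(c_in, hidden, 1, 1, rng, name=f"{name}.cv1")
        self.cv2 = ConvBNReLU(hidden * (1 + len(pool_sizes)), c_out, 1, 1, rng,
                              name=f"{name}.cv2")

    def forward(self, x):
        y = self.cv1(x)
        feats = [y]
        for k in self.pool_sizes:
            feats.append(max_pool2d(feats[-1], k, stride=1))
        return self.cv2(concatenate(feats, axis=1))

    def audit_records(self, h, w):
        recs, h, w = self.cv1.audit_records(h, w)
        r, h, w = self.cv2.audit_records(h, w)
        return recs + r, h, w


# ---------------------------------------------------------------------------
# DySample adaptive upsampling
# ---------------------------------------------------------------------------

class DySample(Module):
    """Point-based adaptive upsampling.

    A linear (1x1) projection of the input produces per-pixel offsets ``O``
    (``2 * groups * scale**2`` channels, pixel-shuffled to the output grid and
    scaled by ``offset_range``); sampling points are ``S = G + O`` with ``G``
    the regular bilinear grid under the half-pixel-center convention, and the
    output is bilinear resampling of the input at ``S`` with border clamping.
    Channels are split into ``groups`` sharing one offset field each.
    """

    def __init__(self, channels: int, rng, scale: int = 2, groups: int = 4,
                 offset_range: float = 0.25, name="dysample"):
        if scale < 2:
            raise ValueError("scale must be an integer >= 2")
        if channels % groups:
            raise ValueError("channels must divide offset groups")
        self.scale = scale
        self.groups = groups
        self.offset_range = offset_range
        self.channels = channels
        self.offset_conv = Conv2dLayer(
            ConvSpec(1, 1, channels, 2 * groups * scale * scale, 1, True),
            rng, name=f"{name}.offset")
        # start from (near) zero offsets: plain bilinear upsampling
        self.offset_conv.weight.data *= 0.01

    def base_grid(self, h: int, w: int) -> np.ndarray:
        """Regular sampling grid in input-pixel units, (Ho, Wo, 2)."""
        s = self.scale
        jj, ii = np.meshgrid(np.arange(w * s), np.arange(h * s))
        gx = (jj + 0.5) / s - 0.5
        gy = (ii + 0.5) / s - 0.5
        return np.stack([gx, gy], axis=-1).astype(np.float32)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        s, g = self.scale, self.groups
        off = self.offset_conv(x)                         # (N, 2*g*s^2, H, W)
        off = off.reshape(n, g, 2, s, s, h, w)
        off = off.transpose(0, 1, 2, 5, 3, 6, 4)          # (N,g,2,H,s,W,s)
        off = off.reshape(n, g, 2, h * s, w * s) * self.offset_range
        grid = Tensor(self.base_grid(h, w))               # (Ho,Wo,2)
        outs = []
        cg = c // g
        for gi in range(g):
            ox = off[:, gi, 0]
            oy = off[:, gi, 1]
            from ._tensor import stack as _stack
            coords = _stack([ox, oy], axis=-1) + grid.reshape(1, h * s, w * s, 2)
            outs.append(grid_sample_bilinear(x[:, gi * cg:(gi + 1) * cg], coords))
        return concatenate(outs, axis=1)

    def audit_records(self, h, w):
        recs, _, _ = self.offset_conv.audit_records(h, w)
        s = self.scale
        # bilinear resampling: 4 MACs per output value
        recs.append({"name": "dysample.resample", "kind": "resample", "spec": None,
                     "params": 0, "flops": 4 * self.channels * h * s * w * s})
        return recs, h * s, w * s


# ---------------------------------------------------------------------------
# iRMB: windowed multi-head self-attention + depthwise convolution
# ---------------------------------------------------------------------------

class IRMB(Module):
    """Inverted residual mobile block.

    Queries come from non-overlapping ``window`` x ``window`` tiles; keys and
    values come from expanded windows (the tile plus a half-window halo, so
    neighbouring tiles overlap).  Multi-head attention output is refined by a
    3x3 depthwise convolution and a pointwise projection, with a residual
    shortcut from the input.
    """

    def __init__(self, channels: int, rng, heads: int = 4, window: int = 7,
                 name: str = "irmb"):
        if channels % heads:
            raise ValueError("channels must be divisible by heads")
        self.channels = channels
        self.heads = heads
        self.window = window
        self.halo = window // 2
        self.q = Conv2dLayer(ConvSpec(1, 1, channels, channels), rng, name=f"{name}.q")
        self.k = Conv2dLayer(ConvSpec(1, 1, channels, channels), rng, name=f"{name}.k")
        self.v = Conv2dLayer(ConvSpec(1, 1, channels, channels), rng, name=f"{name}.v")
        self.dw = ConvBNReLU(channels, channels, 3, 1, rng, groups=channels,
                             name=f"{name}.dw")
        self.proj = ConvBNReLU(channels, channels, 1, 1, rng, act=False,
                               name=f"{name}.proj")

    def attention(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        win, halo = self.window, self.halo
        ke = win + 2 * halo
        ph = (-h) % win
        pw = (-w) % win
        xp = _pad_rb(x, ph, pw) if (ph or pw) else x
        hp, wp = h + ph, w + pw
        nh, nw = hp // win, wp // win
        hd, dk = self.heads, c // self.heads

        q = self.q(xp).reshape(n, hd, dk, nh, win, nw, win)
        q = q.transpose(0, 3, 5, 1, 4, 6, 2).reshape(n * nh * nw * hd, win * win, dk)
        kk = unfold(self.k(xp), ke, stride=win, padding=halo)   # (N,C,nh,nw,ke,ke)
        vv = unfold(self.v(xp), ke, stride=win, padding=halo)
        kk = kk.reshape(n, hd, dk, nh, nw, ke * ke)
        kk = kk.transpose(0, 3, 4, 1, 2, 5).reshape(n * nh * nw * hd, dk, ke * ke)
        vv = vv.reshape(n, hd, dk, nh, nw, ke * ke)
        vv = vv.transpose(0, 3, 4, 1, 5, 2).reshape(n * nh * nw * hd, ke * ke, dk)

        # mask keys that fall in the halo padding outside the feature map
        valid = np.pad(np.ones((1, 1, hp, wp), np.float32),
                       [(0, 0), (0, 0), (halo, halo), (halo, halo)])
        valid = sliding_window_view(valid, (ke, ke), axis=(2, 3))[:, :, ::win, ::win]
        valid = valid.reshape(1, nh * nw, 1, ke * ke)
        bias = np.broadcast_to(np.where(valid > 0, 0.0, -1e9).astype(np.float32),
                               (n, nh * nw, hd, ke * ke))
        bias = bias.reshape(n * nh * nw * hd, 1, ke * ke)
        attn = ((q @ kk) * (1.0 / np.sqrt(dk)) + Tensor(bias)).softmax(axis=-1)
        out = attn @ vv                                          # (B, win^2, dk)
        out = out.reshape(n, nh, nw, hd, win, win, dk)
        out = out.transpose(0, 3, 6, 1, 4, 2, 5).reshape(n, c, hp, wp)
        if ph or pw:
            out = out[:, :, :h, :w]
        return out

    def forward(self, x: Tensor) -> Tensor:
        return x + self.proj(self.dw(self.attention(x)))

    def audit_records(self, h, w):
        recs = []
        for lyr in (self.q, self.k, self.v):
            r, _, _ = lyr.audit_records(h, w)
            recs += r
        win, halo = self.window, self.halo
        ke = win + 2 * halo
        nh, nw = -(-h // win), -(-w // win)
        # q@k and attn@v matrix products, counted as MACs
        mac = 2 * nh * nw * self.heads * (win * win) * (ke * ke) * (self.channels // self.heads)
        recs.append({"name": "irmb.attention", "kind": "attention", "spec": None,
                     "params": 0, "flops": mac})
        for lyr in (self.dw, self.proj):
            r, _, _ = lyr.audit_records(h, w)
            recs += r
        return recs, h, w


def _pad_rb(x: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad bottom/right only (tape-aware)."""
    out = Tensor._make(np.pad(x.data, [(0, 0), (0, 0), (0, ph), (0, pw)]), (x,), None)
    h, w = x.shape[-2:]

    def bw(g):
        if x.requires_grad:
            x._accum(g[..., :h, :w])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Dual-stream fusion
# ---------------------------------------------------------------------------

def fuse_streams(a: Tensor, b: Tensor, lam, mu) -> Tensor:
    """Weighted two-stream combination: (lam*a + 1) + (mu*b + 1).

    ``lam``/``mu`` may be scalars, per-channel vectors or full maps; the
    constant offsets keep both streams active even at zero weight.
    """
    from ._tensor import as_tensor
    return (as_tensor(lam) * a + 1.0) + (as_tensor(mu) * b + 1.0)


class DualStreamFusion(Module):
    """RepNCSPELAN4 stream + iRMB stream, combined per ``fuse_streams`` and
    refined by a confidence-gated pointwise convolution.

    The gate compares the mean absolute activation of the combined map with
    a threshold ``tau``; at the default ``tau = 0`` the refinement branch is
    always taken, keeping the path deterministic under test.
    """

    def __init__(self, c_in: int, c_out: int, hidden: int, rng,
                 heads: int = 4, window: int = 7, tau: float = 0.0,
                 name: str = "fuse"):
        self.elan = RepNCSPELAN4(c_in, c_out, hidden, rng, name=f"{name}.elan")
        self.irmb_in = ConvBNReLU(c_in, c_out, 1, 1, rng, name=f"{name}.pw")
        self.irmb = IRMB(c_out, rng, heads=heads, window=window, name=f"{name}.irmb")
        self.lam = Tensor(np.ones((1, c_out, 1, 1), np.float32), requires_grad=True)
        self.mu = Tensor(np.ones((1, c_out, 1, 1), np.float32), requires_grad=True)
        self.refine = ConvBNReLU(c_out, c_out, 1, 1, rng, name=f"{name}.refine")
        self.tau = tau

    def set_deploy(self, mode=True):
        self.elan.set_deploy(mode)
        return self

    def forward(self, x: Tensor) -> Tensor:
        a = self.elan(x)
        b = self.irmb(self.irmb_in(x))
        fused = fuse_streams(a, b, self.lam, self.mu)
        if float(np.abs(fused.data).mean()) > self.tau:
            fused = self.refine(fused)
        return fused

    def audit_records(self, h, w):
        recs, _, _ = self.elan.audit_records(h, w)
        for sub in (self.irmb_in, self.irmb, self.refine):
            r, _, _ = sub.audit_records(h, w)
            recs += r
        recs.append({"name": "fuse.weights", "kind": "fusion", "spec": None,
                     "params": 2 * self.lam.size, "flops": 2 * self.lam.size * h * w})
        return recs, h, w


# ---------------------------------------------------------------------------
# Neck wiring (three fusion paths)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeckConfig:
    p3_channels: int = 128      # output width of the small-object path
    p4_channels: int = 256
    p5_channels: int = 256      # SPPELAN output width
    sppelan_hidden: int = 128
    elan_hidden_frac: float = 0.5
    heads: int = 4
    window: int = 7
    dysample_groups: int = 4

    @staticmethod
    def from_dict(d: dict) -> "NeckConfig":
        return NeckConfig(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("p3_channels", "p4_channels", "p5_channels", "sppelan_hidden",
                 "elan_hidden_frac", "heads", "window", "dysample_groups")}


class Neck(Module):
    """Wire SPPELAN, DySample, dual-stream fusion and AConv as three paths."""

    def __init__(self, in_channels: tuple[int, int, int], cfg: NeckConfig,
                 rng: np.random.Generator):
        c3, c4, c5 = in_channels
        self.cfg = cfg
        hf = cfg.elan_hidden_frac
        self.sppelan = SPPELAN(c5, cfg.p5_channels, cfg.sppelan_hidden, rng,
                               name="neck.sppelan")
        self.up5 = DySample(cfg.p5_channels, rng, groups=cfg.dysample_groups,
                            name="neck.up5")
        self.fuse4 = DualStreamFusion(cfg.p5_channels + c4, cfg.p4_channels,
                                      max(8, int(cfg.p4_channels * hf)), rng,
                                      heads=cfg.heads, window=cfg.window,
                                      name="neck.fuse4")
        self.up4 = DySample(cfg.p4_channels, rng, groups=cfg.dysample_groups,
                            name="neck.up4")
        self.fuse3 = DualStreamFusion(cfg.p4_channels + c3, cfg.p3_channels,
                                      max(8, int(cfg.p3_channels * hf)), rng,
                                      heads=cfg.heads, window=cfg.window,
                                      name="neck.fuse3")
        self.down3 = AConv(cfg.p3_channels, cfg.p3_channels, rng, name="neck.down3")
        self.elan4 = RepNCSPELAN4(cfg.p3_channels + cfg.p4_channels,
                                  cfg.p4_channels,
                                  max(8, int(cfg.p4_channels * hf)), rng,
                                  name="neck.elan4")
        self.down4 = AConv(cfg.p4_channels, cfg.p4_channels, rng, name="neck.down4")
        self.elan5 = RepNCSPELAN4(cfg.p4_channels + cfg.p5_channels,
                                  cfg.p5_channels,
                                  max(8, int(cfg.p5_channels * hf)), rng,
                                  name="neck.elan5")
        self.out_channels = (cfg.p3_channels, cfg.p4_channels, cfg.p5_channels)

    def set_deploy(self, mode=True):
        for m in (self.fuse4, self.fuse3, self.elan4, self.elan5):
            m.set_deploy(mode)
        return self

    def forward(self, pyramid):
        p3, p4, p5 = pyramid.as_tuple()
        t5 = self.sppelan(p5)
        n4 = self.fuse4(concatenate([self.up5(t5), p4], axis=1))
        n3 = self.fuse3(concatenate([self.up4(n4), p3], axis=1))
        m4 = self.elan4(concatenate([self.down3(n3), n4], axis=1))
        m5 = self.elan5(concatenate([self.down4(m4), t5], axis=1))
        return n3, m4, m5

    def audit_records(self, h3: int, w3: int):
        """Audit with P3 spatial size (h3, w3); P4/P5 are half/quarter."""
        h4, w4, h5, w5 = h3 // 2, w3 // 2, h3 // 4, w3 // 4
        recs = []
        for mod, hh, ww in ((self.sppelan, h5, w5), (self.up5, h5, w5),
                            (self.fuse4, h4, w4), (self.up4, h4, w4),
                            (self.fuse3, h3, w3), (self.down3, h3, w3),
                            (self.elan4, h4, w4), (self.down4, h4, w4),
                            (self.elan5, h5, w5)):
            r, _, _ = mod.audit_records(hh, ww)
            recs += r
        return recs
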