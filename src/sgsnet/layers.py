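"""Layer building blocks: modules, convolutions, batch norm, audit protocol.

Every layer implements ``audit_records(h, w)`` returning its itemized
parameter/FLOP entries plus the output spatial size, so the complexity audit
can walk the architecture graph analytically without running a forward pass.
FLOPs are counted as multiply–accumulate pairs: kernel-area x C_in x C_out
per output pixel for convolutions (no factor 2), with normalization and
attention terms itemized separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, conv2d

__all__ = [
    "ConvSpec", "NormStats", "Module", "Conv2dLayer", "BatchNorm2d",
    "ConvBNReLU", "relu", "batchnorm", "global_avg_pool", "conv_out_size",
]


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of one convolution; parameter count follows K_h*K_w*C_in*C_out."""

    k_h: int
    k_w: int
    c_in: int
    c_out: int
    stride: int = 1
    has_bias: bool = False
    groups: int = 1

    def __post_init__(self):
        if min(self.k_h, self.k_w, self.c_in, self.c_out, self.stride, self.groups) < 1:
            raise ValueError("ConvSpec fields must be positive")
        if self.c_in % self.groups or self.c_out % self.groups:
            raise ValueError("channels must divide groups")

    @property
    def params(self) -> int:
        p = self.k_h * self.k_w * (self.c_in // self.groups) * self.c_out
        return p + (self.c_out if self.has_bias else 0)

    def flops(self, h_out: int, w_out: int) -> int:
        return self.k_h * self.k_w * (self.c_in // self.groups) * self.c_out * h_out * w_out


@dataclass
class NormStats:
    """Per-channel normalization statistics with trainable affine terms."""

    mu: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        if np.any(np.asarray(self.var) < 0):
            raise ValueError("variance must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def conv_out_size(n: int, k: int, stride: int, pad: int | None = None) -> int:
    pad = k // 2 if pad is None else pad
    return (n + 2 * pad - k) // stride + 1


def relu(x: Tensor) -> Tensor:
    return x.relu()


def batchnorm(x: Tensor, stats: NormStats) -> Tensor:
    """Normalize an NCHW tensor with the given per-channel statistics."""
    shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
    mu = np.asarray(stats.mu, np.float32).reshape(shape)
    sd = np.sqrt(np.asarray(stats.var, np.float32) + stats.eps).reshape(shape)
    gamma = np.asarray(stats.gamma, np.float32).reshape(shape)
    beta = np.asarray(stats.beta, np.float32).reshape(shape)
    return (x - mu) * (gamma / sd) + beta


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): mean over the spatial extent of each channel."""
    return x.mean(axis=(2, 3))


class Module:
    """Lightweight container: parameter discovery, train/eval mode, audit."""

    training: bool = True

    @staticmethod
    def _walk(val, name):
        """Yield (name, Module|Tensor) from arbitrarily nested lists/tuples."""
        if isinstance(val, (Module, Tensor)):
            yield name, val
        elif isinstance(val, (list, tuple)):
            for i, item in enumerate(val):
                yield from Module._walk(item, f"{name}.{i}")

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            base = f"{prefix}.{key}" if prefix else key
            for name, item in Module._walk(val, base):
                if isinstance(item, Module):
                    yield from item.named_parameters(name)
                elif item.requires_grad:
                    yield name, item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def set_training(self, mode: bool):
        self.training = mode
        for val in vars(self).values():
            for _, item in Module._walk(val, ""):
                if isinstance(item, Module):
                    item.set_training(mode)
        return self

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()

    def audit_records(self, h: int, w: int):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2dLayer(Module):
    """Plain convolution with He-normal init and the house padding rule."""

    def __init__(self, spec: ConvSpec, rng: np.random.Generator, name: str = "conv"):
        self.spec = spec
        self.name = name
        fan_in = spec.k_h * spec.k_w * spec.c_in // spec.groups
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (spec.c_out, spec.c_in // spec.groups,
                                    spec.k_h, spec.k_w)).astype(np.float32),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(spec.c_out, np.float32), requires_grad=True)
                     if spec.has_bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.spec.stride, groups=self.spec.groups)

    def audit_records(self, h: int, w: int):
        s = self.spec
        ho, wo = conv_out_size(h, s.k_h, s.stride), conv_out_size(w, s.k_w, s.stride)
        rec = {"name": self.name, "kind": "conv", "spec": s,
               "params": s.params, "flops": s.flops(ho, wo)}
        return [rec], ho, wo


class BatchNorm2d(Module):
    """Batch normalization over N,H,W per channel, with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            # fused op differentiating through the batch statistics
            from ._tensor import batchnorm_train
            y, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return y
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        mu = self.running_mean.reshape(1, -1, 1, 1).astype(np.float32)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1).astype(np.float32)
        return (x - mu) * (g * inv) + b

    def audit_records(self, h: int, w: int):
        rec = {"name": self.name, "kind": "batchnorm", "spec": None,
               "params": 2 * self.channels, "flops": 2 * self.channels * h * w}
        return [rec], h, w

    def stats(self) -> NormStats:
        return NormStats(self.running_mean.copy(), self.running_var.copy(),
                         self.gamma.data.copy(), self.beta.data.copy(), self.eps)


class ConvBNReLU(Module):
    """The fixed Conv -> BN -> ReLU ordering used throughout the network."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, groups: int = 1,
                 act: bool = True, name: str = "cbr"):
        self.conv = Conv2dLayer(ConvSpec(k, k, c_in, c_out, stride, False, groups),
                                rng, name=f"{name}.conv")
        self.bn = BatchNorm2d(c_out, name=f"{name}.bn")
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.relu() if self.act else y

    def audit_records(self, h: int, w: int):
        recs, h, w = self.conv.audit_records(h, w)
        r2, h, w = self.bn.audit_records(h, w)
        return recs + r2, h, w
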