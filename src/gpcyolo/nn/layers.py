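"""Detector building blocks.

The lightweight design rests on three ideas:

* **GSConv** — produce half the output channels with a dense convolution,
  derive the other half from them with a cheap 5x5 depthwise pass, then
  interleave ("shuffle") the two halves.  Cost approaches half of a dense
  convolution as the input width grows.
* **PConv** (partial convolution) — convolve only a quarter of the channels
  (3x3, no norm, no bias) and pass the rest through untouched; used inside
  the C2f bottlenecks ("C2f-PC"), cutting their cost to ~1/16.
* **SimAM** — a parameter-free attention weight per activation derived from
  an energy function on per-channel statistics.

Every block is a :class:`Module` over the NumPy autodiff engine and also
knows how to report its own parameter count and profiling cost.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .tensor import Parameter, Tensor, concat

__all__ = [
    "Module", "ConvBNAct", "GSConv", "PConv", "Bottleneck", "PCBottleneck",
    "C2f", "SPPF", "SimAM", "Upsample", "Concat", "Detect", "channel_shuffle",
]

# profiling op-cost model (FLOPs): convolutions count 2 ops per
# multiply-accumulate; each conv-output element additionally pays for the
# (unfused) batch norm (4 ops) and the SiLU activation (6 ops: a sigmoid
# and a product).  This is the convention under which the whole-model
# numbers quoted in the docs are stated.
BN_FLOPS_PER_ELEM = 4
ACT_FLOPS_PER_ELEM = 6


class Module:
    """Minimal module container: tracks parameters, buffers, submodules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def param_count(self) -> int:
        """Number of weight scalars (includes frozen weights such as the
        distribution-focal projection, matching common model summaries)."""
        return sum(p.data.size for p in self.parameters())

    def train(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    # -- state --------------------------------------------------------
    def state_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k, b in self._buffers.items():
            out[prefix + k] = b
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            key = prefix + k
            if key not in state:
                raise KeyError(f"missing weight '{key}' in checkpoint")
            arr = np.asarray(state[key], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for '{key}': checkpoint {arr.shape}, model {p.data.shape}")
            p.data = arr
        for k in self._buffers:
            key = prefix + k
            if key not in state:
                raise KeyError(f"missing buffer '{key}' in checkpoint")
            self._set_buffer(k, np.asarray(state[key], dtype=np.float32))
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- profiling hooks (overridden by leaf blocks) -------------------
    def flops(self, h: int, w: int) -> Tuple[int, Tuple[int, int]]:
        raise NotImplementedError

    def out_channels(self) -> int:
        raise NotImplementedError


def _conv_init(rng: np.random.Generator, c2: int, c1g: int, k: int) -> np.ndarray:
    fan_in = c1g * k * k
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=(c2, c1g, k, k)).astype(np.float32)


class BatchNorm2d(Module):
    """Batch normalization with affine weights and running statistics."""

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        # running stats are bias-corrected exponential averages (divide by
        # 1 - (1-m)^t at eval time), so they are meaningful after only a
        # handful of updates as well as in the long-run limit
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.zeros(c, dtype=np.float32))
        self.register_buffer("num_batches", np.zeros(1, dtype=np.float32))

    def reset_running_stats(self) -> None:
        self._set_buffer("running_mean", np.zeros(self.c, dtype=np.float32))
        self._set_buffer("running_var", np.zeros(self.c, dtype=np.float32))
        self._set_buffer("num_batches", np.zeros(1, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data.reshape(-1))
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * unbiased)
            self._set_buffer("num_batches", self.num_batches + 1)
            xhat = xc * ((var + self.eps) ** -0.5)
            return xhat * self.weight.reshape(1, self.c, 1, 1) \
                + self.bias.reshape(1, self.c, 1, 1)
        t = float(self.num_batches[0])
        corr = 1.0 - (1.0 - self.momentum) ** t if t > 0 else 1.0
        rmean = self.running_mean / corr
        rvar = self.running_var / corr if t > 0 else np.ones_like(self.running_var)
        scale = self.weight.data / np.sqrt(rvar + self.eps)
        shift = self.bias.data - rmean * scale
        return x * Tensor(scale.reshape(1, self.c, 1, 1)) \
            + Tensor(shift.reshape(1, self.c, 1, 1))


class ConvBNAct(Module):
    """Convolution (no bias) + batch norm + SiLU, the stock conv block."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: Optional[int] = None, g: int = 1, act: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = k // 2 if p is None else p
        self.act = act
        self.weight = Parameter(_conv_init(rng, c2, c1 // g, k))
        self.bn = BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.c1:
            raise ValueError(f"expected {self.c1} input channels, got {x.data.shape[1]}")
        y = self.bn(x.conv2d(self.weight, stride=self.s, padding=self.p, groups=self.g))
        return y.silu() if self.act else y

    def out_channels(self) -> int:
        return self.c2

    def flops(self, h, w):
        oh = (h + 2 * self.p - self.k) // self.s + 1
        ow = (w + 2 * self.p - self.k) // self.s + 1
        macs = self.k * self.k * (self.c1 // self.g) * self.c2 * oh * ow
        elems = self.c2 * oh * ow
        f = 2 * macs + BN_FLOPS_PER_ELEM * elems
        if self.act:
            f += ACT_FLOPS_PER_ELEM * elems
        return f, (oh, ow)


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Interleave channel groups: (g, c/g) -> (c/g, g) permutation."""
    n, c, h, w = x.data.shape
    return (x.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


class GSConv(Module):
    """Half dense / half depthwise convolution with a channel shuffle."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, *,
                 rng: np.random.Generator, dw_k: int = 5):
        super().__init__()
        if c2 % 2 != 0:
            raise ValueError(f"GSConv output channels must be even, got {c2}")
        self.c1, self.c2 = c1, c2
        c_ = c2 // 2
        self.cv1 = ConvBNAct(c1, c_, k, s, rng=rng)
        self.cv2 = ConvBNAct(c_, c_, dw_k, 1, g=c_, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        a = self.cv1(x)
        b = self.cv2(a)
        return channel_shuffle(concat([a, b], axis=1), groups=2)

    def out_channels(self) -> int:
        return self.c2

    def flops(self, h, w):
        f1, hw = self.cv1.flops(h, w)
        f2, hw = self.cv2.flops(*hw)
        return f1 + f2, hw


class PConv(Module):
    """Partial convolution: 3x3 over the first ``Cp = C * ratio`` channels
    (no norm, no bias), identity on the remaining channels."""

    def __init__(self, c: int, ratio: float = 0.25, k: int = 3, *,
                 rng: np.random.Generator):
        super().__init__()
        cp = int(c * ratio)
        if cp <= 0 or c * ratio != cp:
            raise ValueError(
                f"channel count {c} is not divisible by the partial ratio {ratio}")
        self.c, self.cp, self.k = c, cp, k
        self.weight = Parameter(_conv_init(rng, cp, cp, k))

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.c:
            raise ValueError(f"expected {self.c} input channels, got {x.data.shape[1]}")
        head = x[:, : self.cp].conv2d(self.weight, stride=1, padding=self.k // 2)
        return concat([head, x[:, self.cp:]], axis=1)

    def out_channels(self) -> int:
        return self.c

    def flops(self, h, w):
        return 2 * self.k * self.k * self.cp * self.cp * h * w, (h, w)


class Bottleneck(Module):
    """Stock residual bottleneck: two 3x3 conv blocks."""

    def __init__(self, c: int, shortcut: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.shortcut = shortcut
        self.cv1 = ConvBNAct(c, c, 3, rng=rng)
        self.cv2 = ConvBNAct(c, c, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y

    def flops(self, h, w):
        return self.cv1.flops(h, w)[0] + self.cv2.flops(h, w)[0], (h, w)


class PCBottleneck(Module):
    """Bottleneck with both dense convolutions replaced by partial ones."""

    def __init__(self, c: int, shortcut: bool = True, ratio: float = 0.25, *,
                 rng: np.random.Generator):
        super().__init__()
        self.shortcut = shortcut
        self.cv1 = PConv(c, ratio, rng=rng)
        self.cv2 = PConv(c, ratio, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y

    def flops(self, h, w):
        return self.cv1.flops(h, w)[0] + self.cv2.flops(h, w)[0], (h, w)


class C2f(Module):
    """Split-transform-concat feature block with ``n`` bottlenecks whose
    outputs are accumulated into the final 1x1 fusion.  ``pc=True`` builds
    the PConv ("C2f-PC") variant."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False,
                 pc: bool = False, *, rng: np.random.Generator):
        super().__init__()
        self.c1, self.c2, self.n = c1, c2, n
        self.c = c2 // 2
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNAct((2 + n) * self.c, c2, 1, rng=rng)
        for i in range(n):
            bn = (PCBottleneck if pc else Bottleneck)(self.c, shortcut, rng=rng)
            setattr(self, f"m{i}", bn)

    def _bottlenecks(self) -> List[Module]:
        return [getattr(self, f"m{i}") for i in range(self.n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        ys = [y[:, : self.c], y[:, self.c:]]
        for m in self._bottlenecks():
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))

    def out_channels(self) -> int:
        return self.c2

    def flops(self, h, w):
        f = self.cv1.flops(h, w)[0] + self.cv2.flops(h, w)[0]
        for m in self._bottlenecks():
            f += m.flops(h, w)[0]
        return f, (h, w)


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c1: int, c2: int, k: int = 5, *, rng: np.random.Generator):
        super().__init__()
        self.c1, self.c2, self.k = c1, c2, k
        c_ = c1 // 2
        self.cv1 = ConvBNAct(c1, c_, 1, rng=rng)
        self.cv2 = ConvBNAct(c_ * 4, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(y[-1].maxpool2d(self.k, 1, self.k // 2))
        return self.cv2(concat(y, axis=1))

    def out_channels(self) -> int:
        return self.c2

    def flops(self, h, w):
        return self.cv1.flops(h, w)[0] + self.cv2.flops(h, w)[0], (h, w)


class SimAM(Module):
    """Parameter-free attention.

    Each activation is weighted by ``sigmoid(e)`` where the energy
    ``e = (x - mu)^2 / (4 * (sigma^2 + lambda)) + 0.5`` is computed from the
    per-channel spatial mean and variance (variance over ``H*W - 1``).
    Contributes exactly zero learnable parameters.  Inputs with a single
    spatial position pass through unchanged (no variance is defined).
    """

    def __init__(self, lambda_reg: float = 1e-4):
        super().__init__()
        if lambda_reg <= 0:
            raise ValueError("lambda_reg must be positive")
        self.lambda_reg = lambda_reg

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if h * w < 2:
            return x
        npos = h * w - 1
        mu = x.mean(axis=(2, 3), keepdims=True)
        d = x - mu
        d2 = d * d
        denom = d2.sum(axis=(2, 3), keepdims=True) * (1.0 / npos) + self.lambda_reg
        energy = d2 / (4.0 * denom) + 0.5
        return x * energy.sigmoid()

    def out_channels(self) -> int:
        raise RuntimeError("SimAM preserves its input channel count")

    def flops(self, h, w):
        return 0, (h, w)  # attention cost excluded from the conv-op budget


class Upsample(Module):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2x()

    def flops(self, h, w):
        return 0, (2 * h, 2 * w)


class Concat(Module):
    """Channel concatenation of multiple inputs."""

    def forward(self, xs: List[Tensor]) -> Tensor:
        return concat(xs, axis=1)

    def flops(self, h, w):
        return 0, (h, w)


class Detect(Module):
    """Anchor-free decoupled detection head with a distribution-focal box
    branch (16 bins per side).  One stem pair per input scale."""

    REG_MAX = 16

    def __init__(self, nc: int, ch: Tuple[int, ...], strides: Tuple[int, ...] = (8, 16, 32),
                 *, rng: np.random.Generator):
        super().__init__()
        self.nc = nc
        self.ch = tuple(ch)
        self.strides = tuple(strides)
        reg = self.REG_MAX
        c2 = max(16, ch[0] // 4, reg * 4)
        c3 = max(ch[0], min(nc, 100))
        self.c2, self.c3 = c2, c3
        for i, c in enumerate(ch):
            setattr(self, f"box{i}a", ConvBNAct(c, c2, 3, rng=rng))
            setattr(self, f"box{i}b", ConvBNAct(c2, c2, 3, rng=rng))
            setattr(self, f"box{i}w", Parameter(_conv_init(rng, 4 * reg, c2, 1)))
            setattr(self, f"box{i}bias", Parameter(np.full(4 * reg, 1.0, dtype=np.float32)))
            setattr(self, f"cls{i}a", ConvBNAct(c, c3, 3, rng=rng))
            setattr(self, f"cls{i}b", ConvBNAct(c3, c3, 3, rng=rng))
            setattr(self, f"cls{i}w", Parameter(_conv_init(rng, nc, c3, 1)))
            # prior: roughly 5 objects per 640x640 image at this stride
            prior = math.log(5.0 / nc / (640.0 / self.strides[i]) ** 2)
            setattr(self, f"cls{i}bias", Parameter(np.full(nc, prior, dtype=np.float32)))
        # distribution-focal projection (frozen, but part of the weight count)
        proj = Parameter(np.arange(reg, dtype=np.float32).reshape(1, reg, 1, 1))
        proj.requires_grad = False
        self.proj = proj

    def forward(self, xs: List[Tensor]) -> List[Tensor]:
        """Per-scale raw maps of shape (N, 4*REG_MAX + nc, H, W)."""
        if len(xs) != len(self.ch):
            raise ValueError(f"expected {len(self.ch)} feature scales, got {len(xs)}")
        outs = []
        for i, x in enumerate(xs):
            b = getattr(self, f"box{i}b")(getattr(self, f"box{i}a")(x))
            b = b.conv2d(getattr(self, f"box{i}w"), getattr(self, f"box{i}bias"))
            c = getattr(self, f"cls{i}b")(getattr(self, f"cls{i}a")(x))
            c = c.conv2d(getattr(self, f"cls{i}w"), getattr(self, f"cls{i}bias"))
            outs.append(concat([b, c], axis=1))
        return outs

    def flops_scale(self, i: int, h: int, w: int) -> int:
        reg = self.REG_MAX
        f = getattr(self, f"box{i}a").flops(h, w)[0]
        f += getattr(self, f"box{i}b").flops(h, w)[0]
        f += 2 * self.c2 * 4 * reg * h * w + 4 * reg * h * w
        f += getattr(self, f"cls{i}a").flops(h, w)[0]
        f += getattr(self, f"cls{i}b").flops(h, w)[0]
        f += 2 * self.c3 * self.nc * h * w + self.nc * h * w
        f += 2 * reg * 4 * h * w  # distribution-focal expectation
        return f
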