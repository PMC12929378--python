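"""Layer abstractions over the autograd engine: Conv2d, BatchNorm2d, the
fused Conv-BN-SiLU building block, Linear, Sequential and a momentum-SGD
optimizer.  Parameter initialisation is seeded explicitly — every module tree
is built from a ``numpy.random.Generator`` so runs are reproducible."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ConvBnAct",
    "Linear",
    "Sequential",
    "SGD",
]


class Module:
    """Base class; tracks sub-modules and parameters by attribute assignment."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n in getattr(self, "_buffer_names", ()):
            yield prefix + n, getattr(self, n)
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        sd = {n: p.data.copy() for n, p in self.named_parameters()}
        sd.update({n: b.copy() for n, b in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict) -> None:
        for n, p in self.named_parameters():
            p.data[...] = sd[n]
        for m_prefix_name, _ in self.named_buffers():
            pass
        # assign buffers (arrays replaced in-place where possible)
        for name, arr in sd.items():
            obj = self
            parts = name.split(".")
            for part in parts[:-1]:
                obj = getattr(obj, part)
            leaf = parts[-1]
            cur = getattr(obj, leaf, None)
            if isinstance(cur, np.ndarray):
                cur[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Tensor(
            _kaiming(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    """Per-channel batch normalization (eps 1e-5, momentum 0.03)."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.03, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        object.__setattr__(self, "_buffer_names", ("running_mean", "running_var"))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv.reshape(1, -1, 1, 1))
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ConvBnAct(Module):
    """3×3/1×1 convolution + batch norm + SiLU — the YOLO 'Conv' block."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        act: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, groups, bias=False, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (in_f, out_f), in_f, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import matmul

        y = matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._seq)

    def __len__(self):
        return len(self._seq)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x


class SGD:
    """SGD with classical momentum and optional weight decay."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (self.lr * v).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
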