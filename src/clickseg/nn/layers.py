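"""Layer abstractions over the autograd engine.

Parameters are held as :class:`~clickseg.nn.autograd.Tensor` objects; modules
register children automatically via attribute assignment (a light-weight
version of the convention used by the big deep-learning frameworks) so a model
can enumerate, save and restore its full state by dotted names.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {state[name].shape}, "
                    f"model {p.data.shape}"
                )
            p.data = state[name].astype(np.float32).copy()
        # Buffers are owned by their module; update in place by path.
        for name, _ in self.named_buffers():
            if name in state:
                self._set_buffer_by_path(name, state[name].copy())

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        parts = path.split(".")
        mod: Module = self
        for p in parts[:-1]:
            mod = mod._children[p]
        mod._buffers[parts[-1]] = value
        object.__setattr__(mod, parts[-1], value)

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
        )


class DepthwiseConv2d(Module):
    def __init__(
        self,
        channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
    ):
        super().__init__()
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = kernel_size * kernel_size
        self.weight = Tensor(
            _he_init(rng, (channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(
            x,
            self.weight,
            None,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
        )


class BatchNorm2d(Module):
    """Standard batch normalisation; running stats with momentum 0.1."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training and ag.is_grad_enabled():
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm[...] = (1 - self.momentum) * rm + self.momentum * mean
            rv[...] = (1 - self.momentum) * rv + self.momentum * var
            return self._norm_train(x, mean, var)
        mean = self._buffers["running_mean"]
        var = self._buffers["running_var"]
        scale = self.weight.data / np.sqrt(var + self.eps)
        shift = self.bias.data - mean * scale
        y = ag.mul(x, Tensor(scale[None, :, None, None]))
        return ag.add(y, Tensor(shift[None, :, None, None]))

    def _norm_train(self, x: Tensor, mean: np.ndarray, var: np.ndarray) -> Tensor:
        gamma, beta = self.weight, self.bias
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
        n_elem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def backward(go):
            if beta.requires_grad:
                beta._accumulate(go.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accumulate((go * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxhat = go * gamma.data[None, :, None, None]
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (inv[None, :, None, None] / n_elem) * (
                    n_elem * gxhat - s1 - xhat * s2
                )
                x._accumulate(dx.astype(np.float32))

        return ag._node(out_data.astype(np.float32), (x, gamma, beta), backward)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            _he_init(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._order = [f"m{i}" for i in range(len(modules))]

    def forward(self, x: Tensor) -> Tensor:
        for name in self._order:
            x = self._children[name](x)
        return x


class ConvBNReLU(Module):
    """3x3 (or 1x1) convolution + batch norm + ReLU, the workhorse block."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        relu: bool = True,
    ):
        super().__init__()
        padding = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(
            in_channels,
            out_channels,
            kernel_size,
            rng,
            stride=stride,
            padding=padding,
            dilation=dilation,
            bias=False,
        )
        self.bn = BatchNorm2d(out_channels)
        self.use_relu = relu

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return ag.relu(y) if self.use_relu else y


class SeparableConvBNReLU(Module):
    """Depthwise 3x3 + pointwise 1x1, each followed by batch norm."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        relu: bool = True,
    ):
        super().__init__()
        padding = dilation
        self.depthwise = DepthwiseConv2d(
            in_channels, 3, rng, stride=stride, padding=padding, dilation=dilation
        )
        self.bn_dw = BatchNorm2d(in_channels)
        self.pointwise = Conv2d(in_channels, out_channels, 1, rng, bias=False)
        self.bn_pw = BatchNorm2d(out_channels)
        self.use_relu = relu

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn_dw(self.depthwise(x))
        y = self.bn_pw(self.pointwise(y))
        return ag.relu(y) if self.use_relu else y
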