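"""Neural-network layers on top of the autodiff engine.

Layers follow the V-Net convention: convolutions carry biases, batch
normalization has affine terms, activations are per-channel PReLU.
Weight initialization is Kaiming (He) normal with fan-in scaling, the
standard choice for rectifier-family activations.
"""

from __future__ import annotations

import numpy as np

from . import autodiff
from .autodiff import Tensor, batchnorm, conv1x1, conv3x3, down2x2, prelu, up2x2


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (trainable + running stats), in a stable order."""
        arrays: list[np.ndarray] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                arrays.append(v.data)
            elif isinstance(v, Module):
                arrays.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
            elif isinstance(v, np.ndarray):
                arrays.append(v)
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state size mismatch")
        for dst, src in zip(own, arrays):
            np.copyto(dst, src)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return w.astype(autodiff.DEFAULT_DTYPE)


class Conv3x3(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Tensor(_kaiming(rng, (cout, cin, 3, 3), 9 * cin), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3x3(x, self.w, self.b)


class Conv1x1(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Tensor(_kaiming(rng, (cout, cin), cin), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1x1(x, self.w, self.b)


class DownConv(Module):
    """2x2 stride-2 convolution halving the in-plane grid."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Tensor(_kaiming(rng, (cout, cin, 2, 2), 4 * cin), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return down2x2(x, self.w, self.b)


class UpConv(Module):
    """2x2 stride-2 transposed convolution doubling the in-plane grid."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Tensor(_kaiming(rng, (cin, cout, 2, 2), 4 * cin), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return up2x2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            out, mu, var = batchnorm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - scale * self.running_mean
        return x * Tensor(scale[None, :, None, None]) + \
            Tensor(shift[None, :, None, None])


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.a = Tensor(np.full(channels, init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.a)


class BottleneckBlock(Module):
    """Residual bottleneck: 1x1 reduce -> 3x3 -> 1x1 expand, skip addition.

    The 1x1 layers shrink the feature maps by `ratio` so the expensive 3x3
    convolution runs on a narrow representation, keeping the model small.
    """

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        mid = max(channels // ratio, 1)
        self.reduce = Conv1x1(channels, mid, rng)
        self.bn1 = BatchNorm2d(mid)
        self.act1 = PReLU(mid)
        self.conv = Conv3x3(mid, mid, rng)
        self.bn2 = BatchNorm2d(mid)
        self.act2 = PReLU(mid)
        self.expand = Conv1x1(mid, channels, rng)
        self.bn3 = BatchNorm2d(channels)
        self.act3 = PReLU(channels)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = self.act1(self.bn1(self.reduce(x), train))
        h = self.act2(self.bn2(self.conv(h), train))
        h = self.bn3(self.expand(h), train)
        return self.act3(h + x)


class Adam:
    """Adaptive moment estimation with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
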