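"""2D VB-Net: a lightweight fully convolutional encoder--decoder.

Five-level V-Net-style architecture for multi-class lesion segmentation on
2D axial slices of thick-slice MRI: a contraction path of residual
bottleneck blocks with 2x2 strided down-convolutions, an expansion path
with 2x2 transposed convolutions, per-level additive skip connections, and
an output head of two convolutional layers followed by a channel softmax.
All kernels are 2D because the source data are acquired with a 2D protocol
(~5 mm slices), where through-plane context is weak.

Block counts are reduced at the deepest levels: with only three output
classes the wide levels do not need many bottleneck structures, and
trimming them keeps the trainable parameter count near one million.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np

from .autodiff import Tensor, softmax_channels
from .layers import (BatchNorm2d, BottleneckBlock, Conv1x1, Conv3x3, DownConv,
                     Module, PReLU, UpConv)

__all__ = ["NetworkConfig", "VBNet2D", "build_network", "count_parameters",
           "default_config", "tiny_config"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the 2D VB-Net."""

    in_channels: int = 3
    out_channels: int = 3
    levels: int = 5
    channels: tuple[int, ...] = (24, 48, 96, 192, 304)
    bottleneck_ratio: int = 4
    enc_blocks: tuple[int, ...] = (1, 2, 3, 2, 2)
    dec_blocks: tuple[int, ...] = (1, 2, 3, 2)
    crop_size: int = 256

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.channels) != self.levels:
            raise ValueError("channels must list one width per level")
        if any(b > a for a, b in zip(self.channels[1:], self.channels)):
            raise ValueError("channel widths must be non-decreasing with depth")
        if len(self.enc_blocks) != self.levels:
            raise ValueError("enc_blocks must list one count per level")
        if len(self.dec_blocks) != self.levels - 1:
            raise ValueError("dec_blocks must list one count per level above the bottom")
        if self.crop_size % (2 ** (self.levels - 1)) != 0:
            raise ValueError(
                f"crop_size {self.crop_size} not divisible by "
                f"2^(levels-1) = {2 ** (self.levels - 1)}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        for k in ("channels", "enc_blocks", "dec_blocks"):
            d[k] = tuple(d[k])
        return cls(**d)


def _load_packaged(name: str) -> NetworkConfig:
    text = resources.files("wmhkit.configs").joinpath(name).read_text()
    return NetworkConfig.from_json(text)


def default_config() -> NetworkConfig:
    """Paper-scale configuration (3 modalities in, 3 classes out, 256 crop)."""
    return _load_packaged("vbnet_default.json")


def tiny_config() -> NetworkConfig:
    """Desk-scale configuration for CPU training on 64x64 phantoms."""
    return _load_packaged("vbnet_tiny.json")


def _block_params(c: int, ratio: int) -> int:
    m = max(c // ratio, 1)
    # 1x1 reduce + BN + PReLU, 3x3 + BN + PReLU, 1x1 expand + BN, PReLU
    return (c * m + m) + 2 * m + m + (9 * m * m + m) + 2 * m + m \
        + (m * c + c) + 2 * c + c


def count_parameters(config: NetworkConfig) -> int:
    """Analytic count of trainable scalars for `config`.

    Counts convolution kernels and biases, batch-norm affine terms, and
    per-channel PReLU slopes. Verified in the test suite against the number
    of scalars held by the instantiated network. Independent of crop_size:
    the network is fully convolutional.
    """
    ch, r = config.channels, config.bottleneck_ratio
    n = 9 * config.in_channels * ch[0] + ch[0] + 2 * ch[0] + ch[0]  # input block
    n += config.enc_blocks[0] * _block_params(ch[0], r)
    for lv in range(1, config.levels):
        a, b = ch[lv - 1], ch[lv]
        n += 4 * a * b + b + 2 * b + b  # down-conv + BN + PReLU
        n += config.enc_blocks[lv] * _block_params(b, r)
    for lv in range(config.levels - 2, -1, -1):
        a, b = ch[lv + 1], ch[lv]
        n += 4 * a * b + b + 2 * b + b  # up-conv + BN + PReLU
        n += config.dec_blocks[lv] * _block_params(b, r)
    # output head: 3x3 conv + BN + PReLU, then 1x1 classifier
    c0, co = ch[0], config.out_channels
    n += 9 * c0 * c0 + c0 + 2 * c0 + c0 + c0 * co + co
    return n


class _Stage(Module):
    """Down- or up-transition followed by bottleneck blocks."""

    def __init__(self, transition: Module, channels: int, n_blocks: int,
                 ratio: int, rng: np.random.Generator):
        self.transition = transition
        self.bn = BatchNorm2d(channels)
        self.act = PReLU(channels)
        self.blocks = [BottleneckBlock(channels, ratio, rng) for _ in range(n_blocks)]

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = self.act(self.bn(self.transition(x), train))
        for blk in self.blocks:
            h = blk(h, train)
        return h


class VBNet2D(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = config.channels
        self.config = config
        self.in_conv = Conv3x3(config.in_channels, ch[0], rng)
        self.in_bn = BatchNorm2d(ch[0])
        self.in_act = PReLU(ch[0])
        self.in_blocks = [BottleneckBlock(ch[0], config.bottleneck_ratio, rng)
                          for _ in range(config.enc_blocks[0])]
        self.encoder = [
            _Stage(DownConv(ch[lv - 1], ch[lv], rng), ch[lv],
                   config.enc_blocks[lv], config.bottleneck_ratio, rng)
            for lv in range(1, config.levels)]
        self.decoder = [
            _Stage(UpConv(ch[lv + 1], ch[lv], rng), ch[lv],
                   config.dec_blocks[lv], config.bottleneck_ratio, rng)
            for lv in range(config.levels - 2, -1, -1)]
        self.out_conv = Conv3x3(ch[0], ch[0], rng)
        self.out_bn = BatchNorm2d(ch[0])
        self.out_act = PReLU(ch[0])
        self.classifier = Conv1x1(ch[0], config.out_channels, rng)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        """Forward pass: (N, Cin, H, W) -> per-class probabilities (N, Cout, H, W)."""
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.config.levels - 1)
        if h % div or w % div:
            raise ValueError(f"in-plane size {h}x{w} not divisible by {div}")
        feat = self.in_act(self.in_bn(self.in_conv(x), train))
        for blk in self.in_blocks:
            feat = blk(feat, train)
        skips = [feat]
        for stage in self.encoder:
            feat = stage(feat, train)
            skips.append(feat)
        for i, stage in enumerate(self.decoder):
            skip = skips[self.config.levels - 2 - i]
            feat = stage.act(stage.bn(stage.transition(feat), train)) + skip
            for blk in stage.blocks:
                feat = blk(feat, train)
        feat = self.out_act(self.out_bn(self.out_conv(feat), train))
        return softmax_channels(self.classifier(feat))


def build_network(config: NetworkConfig, seed: int = 0) -> VBNet2D:
    """Instantiate a seeded, Kaiming-initialized 2D VB-Net."""
    return VBNet2D(config, seed=seed)
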