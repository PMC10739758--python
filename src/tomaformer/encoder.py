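"""Five-level convolutional encoder of shape-preservation and residual blocks.

The encoder stacks 11 shape-preservation blocks (SPBs) and 5 residual
blocks (RBs) over five levels (default 2+1, 2+1, 2+1, 2+1, 3+1). An SPB
keeps spatial resolution and spends exactly 4 convolutions, 4 batch
norms and 2 ReLUs; an RB spends 3 convolutions, 3 batch norms, 2 ReLUs
and one 2x2 max pooling whose argmax indices are kept for the decoder's
unpooling. Each level's pre-pool activation is exported as a skip
feature. Total downsampling is 2^5.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    """Structural hyperparameters of the encoder.

    ``width_multiplier`` scales every level width (floor 1 channel) so
    tiny test models keep the exact block structure.
    """

    level_widths: tuple = (16, 32, 64, 128, 256)
    spb_per_level: tuple = (2, 2, 2, 2, 3)
    rb_per_level: tuple = (1, 1, 1, 1, 1)
    pool_size: int = 2
    width_multiplier: float = 1.0

    def __post_init__(self):
        if len(self.level_widths) != 5 or len(self.spb_per_level) != 5 \
                or len(self.rb_per_level) != 5:
            raise ValueError("encoder has exactly five levels")
        if sum(self.spb_per_level) != 11:
            raise ValueError("shape-preservation blocks must total 11")
        if sum(self.rb_per_level) != 5:
            raise ValueError("residual blocks must total 5")
        for s, r in zip(self.spb_per_level, self.rb_per_level):
            if not 3 <= s + r <= 4:
                raise ValueError("each level carries three to four blocks")
        if self.pool_size != 2:
            raise ValueError("only 2x2 pooling is supported")

    def scaled_widths(self) -> tuple:
        return tuple(max(1, int(round(w * self.width_multiplier)))
                     for w in self.level_widths)


class ShapePreservationBlock(L.Module):
    """Residual block that preserves spatial dims.

    Main path conv-BN-ReLU-conv-BN, projection shortcut conv-BN,
    elementwise sum, ReLU, then a trailing conv-BN:
    exactly {conv: 4, BN: 4, ReLU: 2}.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = L.Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = L.BatchNorm2d(out_channels)
        self.relu1 = L.ReLU()
        self.conv2 = L.Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = L.BatchNorm2d(out_channels)
        self.conv_short = L.Conv2d(in_channels, out_channels, 3, rng)
        self.bn_short = L.BatchNorm2d(out_channels)
        self.relu2 = L.ReLU()
        self.conv3 = L.Conv2d(out_channels, out_channels, 3, rng)
        self.bn3 = L.BatchNorm2d(out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        main = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        short = self.bn_short(self.conv_short(x))
        merged = self.relu2(main + short)
        return self.bn3(self.conv3(merged))


class ResidualBlock(L.Module):
    """Residual block ending in 2x2 stride-2 max pooling.

    Main path conv-BN-ReLU-conv-BN, shortcut conv-BN, sum, ReLU, pool:
    exactly {conv: 3, BN: 3, ReLU: 2, maxpool: 1}. Returns the pooled map,
    the argmax indices, and the pre-pool activation (the skip feature).
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = L.Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = L.BatchNorm2d(out_channels)
        self.relu1 = L.ReLU()
        self.conv2 = L.Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = L.BatchNorm2d(out_channels)
        self.conv_short = L.Conv2d(in_channels, out_channels, 3, rng)
        self.bn_short = L.BatchNorm2d(out_channels)
        self.relu2 = L.ReLU()

    def __call__(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even before pooling, got {h}x{w}")
        main = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        short = self.bn_short(self.conv_short(x))
        prepool = self.relu2(main + short)
        pooled, idx = T.max_pool2x2(prepool)
        return pooled, idx, prepool


def layer_census(module: L.Module) -> dict:
    """Count conv / batch-norm / ReLU / pooling layers inside a module."""
    counts = {"conv": 0, "bn": 0, "relu": 0, "maxpool": 0}
    for m in module.modules():
        if isinstance(m, L.Conv2d):
            counts["conv"] += 1
        elif isinstance(m, L.BatchNorm2d):
            counts["bn"] += 1
        elif isinstance(m, L.ReLU):
            counts["relu"] += 1
        if isinstance(m, ResidualBlock):
            counts["maxpool"] += 1
    return counts


class ConvEncoder(L.Module):
    """Levels E-1..E-5, each its SPBs then its RB; downsampling factor 32."""

    def __init__(self, in_channels: int, config: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        widths = config.scaled_widths()
        self.levels: list[list[L.Module]] = []
        prev = in_channels
        for level in range(5):
            blocks: list[L.Module] = []
            for _ in range(config.spb_per_level[level]):
                blocks.append(ShapePreservationBlock(prev, widths[level], rng))
                prev = widths[level]
            for _ in range(config.rb_per_level[level]):
                blocks.append(ResidualBlock(prev, widths[level], rng))
                prev = widths[level]
            self.levels.append(blocks)
        # flat list so Module.parameters() discovers everything
        self._blocks = [b for level in self.levels for b in level]

    def __call__(self, x: Tensor):
        """Returns (f_e, skips, pool_indices)."""
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial dims must be divisible by 2^5=32, got {h}x{w}")
        skips, indices = [], []
        for blocks in self.levels:
            for block in blocks:
                if isinstance(block, ResidualBlock):
                    x, idx, prepool = block(x)
                    skips.append(prepool)
                    indices.append(idx)
                else:
                    x = block(x)
        return x, skips, indices

    def block_counts(self) -> tuple[int, int]:
        n_spb = sum(isinstance(b, ShapePreservationBlock) for b in self._blocks)
        n_rb = sum(isinstance(b, ResidualBlock) for b in self._blocks)
        return n_spb, n_rb
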