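"""Fusion of convolutional and transformer features, and the decoder.

The transformer projections ``p_t`` are laid back on their patch grid,
bilinearly resized to the latent feature map's spatial dims, projected to
its channel width and applied as a multiplicative gate on ``f_e`` (the
projections literally act as a filter on the convolutional features); a
3x3 convolution then yields the fused features ``f_d``. The decoder
mirrors the encoder with five stages of index-routed max unpooling,
additive skip connections and rescaling units (conv-BN-ReLU), ending in a
1x1 classifier and a per-pixel softmax.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor
from .encoder import ConvEncoder, EncoderConfig
from .transformer import TransformerBranch, TransformerConfig


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Full model configuration.

    ``use_transformer=False`` selects the fully convolutional ablation
    variant (no patch branch, no fusion). ``fusion`` picks multiplicative
    gating (default) or channel concatenation.
    """

    rows: int = 64
    cols: int = 64
    channels: int = 3
    n_classes: int = 4
    use_transformer: bool = True
    fusion: str = "gate"
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    transformer: TransformerConfig = dataclasses.field(default_factory=TransformerConfig)

    def __post_init__(self):
        if self.fusion not in ("gate", "concat"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.rows % 32 or self.cols % 32:
            raise ValueError("input dims must be divisible by 32")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "ModelConfig":
        d = json.loads(text)
        d["encoder"] = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in d["encoder"].items()})
        d["transformer"] = TransformerConfig(**d["transformer"])
        return ModelConfig(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class FeatureFusion(L.Module):
    """f_d from f_e and p_t: grid -> resize -> 1x1 projection -> gate -> 3x3 conv."""

    def __init__(self, token_width: int, token_grid: tuple[int, int],
                 feature_channels: int, mode: str, rng: np.random.Generator):
        super().__init__()
        self.token_grid = token_grid
        self.mode = mode
        self.project = L.Conv2d(token_width, feature_channels, 1, rng, padding=0)
        in_ch = feature_channels * (2 if mode == "concat" else 1)
        self.conv = L.Conv2d(in_ch, feature_channels, 3, rng)

    def __call__(self, f_e: Tensor, p_t: Tensor) -> Tensor:
        n, n_tok, width = p_t.shape
        gr, gc = self.token_grid
        if gr * gc != n_tok:
            raise ValueError(f"{n_tok} tokens do not form a {gr}x{gc} grid")
        grid = p_t.reshape((n, gr, gc, width)).transpose((0, 3, 1, 2))
        resized = T.bilinear_resize(grid, (f_e.shape[2], f_e.shape[3]))
        gate = self.project(resized)
        if self.mode == "concat":
            fused = T.concat([f_e, gate], axis=1)
        else:
            fused = f_e * gate
        return self.conv(fused)


class RescalingUnit(L.Module):
    """Convolution + batch normalization + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = L.Conv2d(in_channels, out_channels, 3, rng)
        self.bn = L.BatchNorm2d(out_channels)
        self.relu = L.ReLU()

    def __call__(self, x: Tensor) -> Tensor:
        return self.relu(self.bn(self.conv(x)))


class Decoder(L.Module):
    """Five mirror stages: unpool by stored indices, add (projected) skip,
    rescale; then a 1x1 classifier and per-pixel softmax."""

    def __init__(self, widths: tuple, n_classes: int, rng: np.random.Generator):
        super().__init__()
        self.widths = widths
        # the mirror pairing keeps skip and unpooled channel widths equal at
        # every stage, so no channel projections are needed
        self.rescalers: list[RescalingUnit] = []
        for level in range(4, -1, -1):           # deepest stage first
            out_ch = widths[level - 1] if level > 0 else widths[0]
            self.rescalers.append(RescalingUnit(widths[level], out_ch, rng))
        self.classifier = L.Conv2d(widths[0], n_classes, 1, rng, padding=0)

    def __call__(self, f_d: Tensor, indices: list, skips: list):
        if len(indices) != 5 or len(skips) != 5:
            raise ValueError("decoder expects five pooling-index/skip records")
        x = f_d
        for stage, level in enumerate(range(4, -1, -1)):
            idx, skip = indices[level], skips[level]
            if x.shape[1] != idx.shape[1]:
                raise ValueError(
                    f"stage {stage}: {x.shape[1]} channels vs pooling indices "
                    f"for {idx.shape[1]} channels")
            x = T.max_unpool2x2(x, idx)
            if x.shape != skip.shape:
                raise ValueError(f"stage {stage}: skip shape {skip.shape} does "
                                 f"not match unpooled {x.shape}")
            x = x + skip
            x = self.rescalers[stage](x)
        logits = self.classifier(x)
        probs = T.softmax(logits, axis=1)
        return logits, probs


class ConvTransformerSegmenter(L.Module):
    """End-to-end segmentation model: conv encoder, optional patch-transformer
    branch fused into the latent features, unpooling decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = ConvEncoder(config.channels, config.encoder, rng)
        widths = config.encoder.scaled_widths()
        if config.use_transformer:
            self.transformer = TransformerBranch(
                config.rows, config.cols, config.channels, config.transformer, rng)
            self.fusion = FeatureFusion(
                config.transformer.width, self.transformer.grid,
                widths[-1], config.fusion, rng)
        self.decoder = Decoder(widths, config.n_classes, rng)

    def __call__(self, x: Tensor):
        """Returns (logits, probability map), both (N, c_se, R, C)."""
        f_e, skips, indices = self.encoder(x)
        if self.config.use_transformer:
            p_t = self.transformer(x)
            f_d = self.fusion(f_e, p_t)
        else:
            f_d = f_e
        return self.decoder(f_d, indices, skips)

    def predict(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Segment one R x C x 3 image (eval mode, no tape). Returns
        (label mask, probability map as R x C x c_se)."""
        self.eval()
        x = Tensor(image.transpose(2, 0, 1)[None])
        with T.no_grad():
            _, probs = self(x)
        p = probs.data[0].transpose(1, 2, 0)
        return p.argmax(axis=-1), p


# -- checkpoint I/O -----------------------------------------------------------

def save_checkpoint(model: ConvTransformerSegmenter, path):
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8),
        __config_hash__=np.frombuffer(model.config.hash().encode(), dtype=np.uint8),
        **state)


def load_checkpoint(path) -> ConvTransformerSegmenter:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        stored_hash = bytes(data["__config_hash__"]).decode()
        config = ModelConfig.from_json(cfg_json)
        if config.hash() != stored_hash:
            raise ValueError("checkpoint config hash mismatch; refusing to load")
        model = ConvTransformerSegmenter(config)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.load_state_dict(state)
    return model
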