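"""Patch-transformer branch.

The input image is tiled into ``n_p`` non-overlapping square patches of
side ``P = sqrt(R*C/n_p)``; each flattened patch gets a learned linear
projection plus a learned positional embedding, and the resulting token
sequence runs through a cascade of ``t`` (default 3) transformer encoders
built around contextual multi-head self-attention (CMSA). The last
encoder's projections ``p_t`` are what the fusion stage combines with the
convolutional features.

A deliberate faithfulness note: the attention scores are scaled by
``1/sqrt(l)`` with ``l`` the full token width, not by ``1/sqrt(d_head)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclasses.dataclass(frozen=True)
class TransformerConfig:
    """Hyperparameters of the patch-transformer branch.

    ``depth`` is the number of cascaded encoders (the cascade's last
    output is ``p_t``); ``width`` the token width ``l``; ``heads`` the
    CMSA head count; ``ff_width`` the hidden width of the feed-forward
    block; ``patch_size`` the patch side ``P`` in pixels.
    """

    depth: int = 3
    width: int = 128
    heads: int = 4
    ff_width: int = 256
    patch_size: int = 8
    ln_eps: float = 1e-5

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("transformer depth must be >= 1 (the fully "
                             "convolutional variant is a separate model flag)")
        if self.width % self.heads:
            raise ValueError(f"width {self.width} not divisible by heads {self.heads}")


def patch_side(rows: int, cols: int, n_patches: int) -> int:
    """P = sqrt(R*C/n_p); errors name the valid choices of n_p."""
    p_sq = rows * cols / n_patches
    p = int(round(np.sqrt(p_sq)))
    if p * p != p_sq or rows % p or cols % p:
        valid = sorted({(rows // s) * (cols // s)
                        for s in range(1, min(rows, cols) + 1)
                        if rows % s == 0 and cols % s == 0})
        raise ValueError(
            f"n_p={n_patches} does not tile a {rows}x{cols} image with square "
            f"patches; valid n_p choices include {valid}")
    return p


def patchify(x: Tensor, n_patches: int) -> Tensor:
    """Tile an NCHW image batch into (N, n_p, P*P*Ch) row-major patches."""
    n, ch, rows, cols = x.shape
    p = patch_side(rows, cols, n_patches)
    gr, gc = rows // p, cols // p
    t = x.reshape((n, ch, gr, p, gc, p))
    t = t.transpose((0, 2, 4, 3, 5, 1))          # (N, gr, gc, P, P, Ch)
    return t.reshape((n, gr * gc, p * p * ch))


def unpatchify(patches: Tensor, rows: int, cols: int, channels: int) -> Tensor:
    """Inverse of :func:`patchify` (exact reassembly)."""
    n, n_p, _ = patches.shape
    p = patch_side(rows, cols, n_p)
    gr, gc = rows // p, cols // p
    t = patches.reshape((n, gr, gc, p, p, channels))
    t = t.transpose((0, 5, 1, 3, 2, 4))          # (N, Ch, gr, P, gc, P)
    return t.reshape((n, channels, rows, cols))


def embed_sequence(patches: Tensor, positional: Tensor, projection: L.Linear) -> Tensor:
    """Token i = linear projection of patch i + positional embedding i."""
    if positional.shape[-1] != projection.weight.shape[1]:
        raise ValueError("positional embedding width differs from projection width")
    return projection(patches) + positional


class CMSAttention(L.Module):
    """Contextual multi-head self-attention over an (N, tokens, l) sequence.

    Per head j: ``A_j = softmax(Q_j K_j^T / sqrt(l)) V_j`` with Q/K/V from
    per-head learned maps; head outputs are concatenated and merged back
    to width l by a learned (bias-free) map.
    """

    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if width % heads:
            raise ValueError("width must be divisible by head count")
        self.width, self.heads = width, heads
        self.d_head = width // heads
        scale = np.sqrt(1.0 / width)
        shape = (heads, width, self.d_head)
        self.w_q = L.Parameter(rng.normal(0, scale, shape))
        self.w_k = L.Parameter(rng.normal(0, scale, shape))
        self.w_v = L.Parameter(rng.normal(0, scale, shape))
        self.w_merge = L.Parameter(rng.normal(0, scale, (width, width)))

    def __call__(self, tokens: Tensor, return_attention: bool = False):
        n, n_tok, l = tokens.shape
        x = tokens.reshape((n, 1, n_tok, l))            # broadcast over heads
        q = x @ self.w_q                                # (N, h, tok, d)
        k = x @ self.w_k
        v = x @ self.w_v
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(l))
        if not np.isfinite(scores.data).all():
            raise FloatingPointError("non-finite attention scores")
        attn = T.softmax(scores, axis=-1)               # rows sum to 1
        out = attn @ v                                  # (N, h, tok, d)
        merged = out.transpose((0, 2, 1, 3)).reshape((n, n_tok, l))
        result = merged @ self.w_merge
        if return_attention:
            return result, attn.data
        return result


class TransformerEncoder(L.Module):
    """One encoder: pre-norm CMSA with residual, then pre-norm feed-forward
    whose residual is the *normalized* attention sum."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.norm1 = L.LayerNorm(config.width, eps=config.ln_eps)
        self.attention = CMSAttention(config.width, config.heads, rng)
        self.norm2 = L.LayerNorm(config.width, eps=config.ln_eps)
        self.ff1 = L.Linear(config.width, config.ff_width, rng)
        self.ff2 = L.Linear(config.ff_width, config.width, rng)

    def feedforward(self, x: Tensor) -> Tensor:
        return self.ff2(T.relu(self.ff1(x)))

    def __call__(self, tokens: Tensor) -> Tensor:
        attended = self.attention(self.norm1(tokens)) + tokens
        normed = self.norm2(attended)
        return self.feedforward(normed) + normed


class TransformerStack(L.Module):
    """Cascade of ``depth`` independent encoders; returns the last one's
    projections p_t."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.encoders = [TransformerEncoder(config, rng) for _ in range(config.depth)]

    def __call__(self, tokens: Tensor) -> Tensor:
        for enc in self.encoders:
            tokens = enc(tokens)
        return tokens


class TransformerBranch(L.Module):
    """Patchify -> embed -> encoder cascade, for a fixed input geometry."""

    def __init__(self, rows: int, cols: int, channels: int,
                 config: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        p = config.patch_size
        if rows % p or cols % p:
            raise ValueError(f"patch size {p} does not divide {rows}x{cols}")
        self.n_patches = (rows // p) * (cols // p)
        self.grid = (rows // p, cols // p)
        patch_dim = p * p * channels
        self.projection = L.Linear(patch_dim, config.width, rng)
        self.positional = L.Parameter(
            rng.normal(0, 0.02, (self.n_patches, config.width)))
        self.stack = TransformerStack(config, rng)

    def __call__(self, x: Tensor) -> Tensor:
        patches = patchify(x, self.n_patches)
        tokens = embed_sequence(patches, self.positional, self.projection)
        return self.stack(tokens)
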