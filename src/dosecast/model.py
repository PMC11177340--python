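"""Progressive-refinement windowed-attention dose prediction network.

Encoder: four stages of windowed token attention.  The input plane is cut
into patch tokens, linearly embedded, and given learnable per-window
position parameters; each stage applies a constant-window attention block,
a shifted-window attention block (cyclic half-window shift with wrap
masking), and a convolutional channel/spatial attention block, with 2x2
patch merging between stages so the token grid halves and the embedding
dimension doubles.

The attention is a weighted variant of scaled dot-product attention: per
head, the score matrix is ``S = tanh(Q + K) @ W_alpha / sqrt(dk)`` with a
learnable ``W_alpha`` of shape (dk, N_w), so the window token count N_w is
fixed by construction; rows of softmax(S) are the attention weights over
the value vectors.

Decoder: four stages of (bilinear x2 upsample, skip concatenation, two
conv3x3-BatchNorm-Mish blocks) at widths ``decoder_channels``.  Each stage
feeds a generation head emitting a one-channel dose map; the four maps form
a pyramid refined coarse-to-fine: ``p_1 = phi_1`` and
``p_i = phi_i + Upsample2x(p_{i-1})``, so each branch learns a residual
correction to the upsampled coarser prediction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .grids import PredictionPyramid

__all__ = [
    "ModelConfig",
    "DosePredictionNet",
    "EnhancedWindowAttention",
    "TransformerBlock",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "DecoderStage",
    "RefineHead",
    "PatchEmbed",
    "PatchMerging",
    "shifted_window_mask",
    "window_partition",
    "window_reverse",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The small default (grid 64, embed 32) is sized for CPU experiments;
    :meth:`clinical_scale` returns the 512-grid configuration with decoder
    widths 512/256/128/64.
    """

    in_channels: int = 33
    grid_size: int = 64
    patch_size: int = 2
    embed_dim: int = 32
    heads: int = 4
    window: int = 4                      # tokens per window side; N_w = window**2
    stage_depths: tuple[int, int, int, int] = (2, 2, 2, 2)
    decoder_channels: tuple[int, int, int, int] = (64, 32, 16, 8)
    mlp_ratio: float = 2.0
    cbam_reduction: int = 4

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        side = self.grid_size // self.patch_size
        if side * self.patch_size != self.grid_size:
            raise ValueError("grid_size must be divisible by patch_size")
        for i in range(4):
            stage_side = side // (2 ** i)
            if stage_side % self.window:
                raise ValueError(
                    f"token grid side {stage_side} at stage {i + 1} not divisible "
                    f"by window {self.window}"
                )
        for d in self.stage_depths:
            if d < 1 or d % 2:
                raise ValueError("stage depths must be positive and even (W/SW pairs)")

    @property
    def n_w(self) -> int:
        return self.window ** 2

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def stage_dims(self) -> tuple[int, int, int, int]:
        return tuple(self.embed_dim * 2 ** i for i in range(4))

    @classmethod
    def clinical_scale(cls) -> "ModelConfig":
        return cls(grid_size=512, patch_size=4, embed_dim=96, heads=6,
                   window=8, decoder_channels=(512, 256, 128, 64))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_depths", "decoder_channels"):
            d[key] = tuple(d[key])
        return cls(**d)


# -- token plumbing --------------------------------------------------------

def window_partition(x: ad.Tensor, w: int) -> ad.Tensor:
    """(B, H, W, C) token grid -> (B, nW, w*w, C) window sequences."""
    B, H, W, C = x.shape
    x = ad.reshape(x, (B, H // w, w, W // w, w, C))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (B, (H // w) * (W // w), w * w, C))


def window_reverse(x: ad.Tensor, w: int, H: int, W: int) -> ad.Tensor:
    """Inverse of :func:`window_partition`."""
    B = x.shape[0]
    C = x.shape[-1]
    x = ad.reshape(x, (B, H // w, W // w, w, w, C))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (B, H, W, C))


def shifted_window_mask(side: int, w: int, shift: int) -> np.ndarray:
    """Additive attention mask (nW, N_w, N_w) for cyclically shifted windows.

    Region labels partition the canvas so that, after the (-shift, -shift)
    roll, tokens wrapped from opposite edges land in the same window but in
    different regions; pairs from different regions get -1e9.
    """
    img = np.zeros((side, side))
    slices = (slice(0, -w), slice(-w, -shift), slice(-shift, None))
    cnt = 0
    for hs in slices:
        for ws in slices:
            img[hs, ws] = cnt
            cnt += 1
    n = side // w
    wins = img.reshape(n, w, n, w).transpose(0, 2, 1, 3).reshape(n * n, w * w)
    mask = np.where(wins[:, :, None] != wins[:, None, :], -1e9, 0.0)
    return mask.astype(np.float32)


# -- encoder modules -------------------------------------------------------

class PatchEmbed(ad.Module):
    """Patch split, linear projection, and learnable per-window positions.

    One position table of shape (window, window, Ce) is shared across all
    windows of the token grid.
    """

    def __init__(self, rng, config: ModelConfig):
        P, C, Ce = config.patch_size, config.in_channels, config.embed_dim
        self.proj = ad.Linear(rng, C * P * P, Ce)
        self.pos = ad.Tensor(
            np.zeros((1, 1, config.window, 1, config.window, Ce), dtype=np.float32),
            requires_grad=True,
        )
        self.patch = P
        self.window = config.window

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        """(B, C, H, W) image -> (B, H/P, W/P, Ce) token grid."""
        B, C, H, W = x.shape
        P = self.patch
        t = ad.reshape(x, (B, C, H // P, P, W // P, P))
        t = ad.transpose(t, (0, 2, 4, 1, 3, 5))
        t = ad.reshape(t, (B, H // P, W // P, C * P * P))
        t = self.proj(t)
        side, w, Ce = H // P, self.window, t.shape[-1]
        t = ad.reshape(t, (B, side // w, w, side // w, w, Ce))
        t = ad.add(t, self.pos)
        return ad.reshape(t, (B, side, side, Ce))


class PatchMerging(ad.Module):
    """2x2 token concatenation + linear halving the grid, doubling channels."""

    def __init__(self, rng, dim: int):
        self.reduce = ad.Linear(rng, 4 * dim, 2 * dim)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        B, H, W, C = x.shape
        x = ad.reshape(x, (B, H // 2, 2, W // 2, 2, C))
        x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
        x = ad.reshape(x, (B, H // 2, W // 2, 4 * C))
        return self.reduce(x)


class EnhancedWindowAttention(ad.Module):
    """Multi-head attention with learnable score map W_alpha per head.

    Q, K, V are bias-free projections; per head the N_w x N_w score matrix
    is ``tanh(Q + K) @ W_alpha / sqrt(dk)`` and its row-softmax weights the
    value vectors.  Heads are concatenated without an output projection.
    """

    def __init__(self, rng, dim: int, heads: int, n_w: int):
        dk = dim // heads
        self.w_q = ad.Tensor(_init(rng, (heads, dim, dk)), requires_grad=True)
        self.w_k = ad.Tensor(_init(rng, (heads, dim, dk)), requires_grad=True)
        self.w_v = ad.Tensor(_init(rng, (heads, dim, dk)), requires_grad=True)
        self.w_alpha = ad.Tensor(_init(rng, (heads, dk, n_w)), requires_grad=True)
        self.heads, self.dk, self.n_w = heads, dk, n_w

    def forward(self, x: ad.Tensor, mask: np.ndarray | None = None) -> ad.Tensor:
        """(B, nW, N_w, C) windows -> same shape; optional additive mask
        (nW, N_w, N_w) applied before the softmax."""
        B, nW, N, C = x.shape
        if N != self.n_w:
            raise ValueError(f"window has {N} tokens but W_alpha expects {self.n_w}")
        xh = ad.reshape(x, (B, nW, 1, N, C))
        q = ad.matmul(xh, self.w_q)                      # (B, nW, h, N, dk)
        k = ad.matmul(xh, self.w_k)
        v = ad.matmul(xh, self.w_v)
        scores = ad.matmul(ad.tanh(q + k), self.w_alpha) * (1.0 / np.sqrt(self.dk))
        if mask is not None:
            scores = ad.add(scores, mask[None, :, None, :, :])
        attn = ad.softmax(scores, axis=-1)               # rows sum to 1
        out = ad.matmul(attn, v)                         # (B, nW, h, N, dv)
        out = ad.transpose(out, (0, 1, 3, 2, 4))
        return ad.reshape(out, (B, nW, N, C))

    def attention_weights(self, x: ad.Tensor, mask: np.ndarray | None = None) -> np.ndarray:
        """Softmax attention matrices (diagnostics; no tape)."""
        with ad.no_grad():
            B, nW, N, C = x.shape
            xh = ad.reshape(x, (B, nW, 1, N, C))
            q = ad.matmul(xh, self.w_q)
            k = ad.matmul(xh, self.w_k)
            scores = ad.matmul(ad.tanh(q + k), self.w_alpha) * (1.0 / np.sqrt(self.dk))
            if mask is not None:
                scores = ad.add(scores, mask[None, :, None, :, :])
            return ad.softmax(scores, axis=-1).data


def _init(rng, shape):
    fan = shape[-2]
    return rng.normal(0.0, np.sqrt(1.0 / fan), size=shape).astype(np.float32)


class Mlp(ad.Module):
    def __init__(self, rng, dim: int, ratio: float):
        hidden = int(dim * ratio)
        self.fc1 = ad.Linear(rng, dim, hidden)
        self.fc2 = ad.Linear(rng, hidden, dim)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        return self.fc2(ad.mish(self.fc1(x)))


class TransformerBlock(ad.Module):
    """Pre-norm residual attention + pre-norm residual MLP on a token grid.

    ``shift`` > 0 selects the shifted-window variant: the token grid is
    cyclically rolled by (-shift, -shift), windows are attended under the
    wrap mask, and the roll is undone afterwards.
    """

    def __init__(self, rng, dim: int, heads: int, window: int, side: int,
                 shift: int, mlp_ratio: float):
        self.norm1 = ad.LayerNorm(dim)
        self.attn = EnhancedWindowAttention(rng, dim, heads, window ** 2)
        self.norm2 = ad.LayerNorm(dim)
        self.mlp = Mlp(rng, dim, mlp_ratio)
        self.window, self.shift, self.side = window, shift, side
        self.mask = shifted_window_mask(side, window, shift) if shift else None

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        B, H, W, C = x.shape
        h = self.norm1(x)
        if self.shift:
            h = ad.roll(h, (-self.shift, -self.shift), axis=(1, 2))
        h = window_partition(h, self.window)
        h = self.attn(h, self.mask)
        h = window_reverse(h, self.window, H, W)
        if self.shift:
            h = ad.roll(h, (self.shift, self.shift), axis=(1, 2))
        x = ad.add(x, h)                       # residual attention
        return ad.add(x, self.mlp(self.norm2(x)))   # residual MLP


class ChannelAttention(ad.Module):
    """Sigmoid channel weights from a shared MLP over global avg/max pools."""

    def __init__(self, rng, dim: int, reduction: int):
        hidden = max(dim // reduction, 1)
        self.fc1 = ad.Linear(rng, dim, hidden)
        self.fc2 = ad.Linear(rng, hidden, dim)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        avg = ad.tmean(x, axis=(2, 3))
        mx = ad.tmax(x, axis=(2, 3))
        mlp = lambda d: self.fc2(ad.relu(self.fc1(d)))  # noqa: E731
        weights = ad.sigmoid(ad.add(mlp(avg), mlp(mx)))
        B, C = weights.shape
        return ad.mul(x, ad.reshape(weights, (B, C, 1, 1)))


class SpatialAttention(ad.Module):
    """Sigmoid per-pixel weights from a 7x7 conv over channel mean/max maps."""

    def __init__(self, rng):
        self.conv = ad.Conv2d(rng, 2, 1, 7, padding=3)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        avg = ad.tmean(x, axis=1, keepdims=True)
        mx = ad.tmax(x, axis=1, keepdims=True)
        weights = ad.sigmoid(self.conv(ad.concat([avg, mx], axis=1)))
        return ad.mul(x, weights)


class CBAM(ad.Module):
    """Residual channel-then-spatial attention: x + Ms(Mc(x) * x) * ..."""

    def __init__(self, rng, dim: int, reduction: int):
        self.channel = ChannelAttention(rng, dim, reduction)
        self.spatial = SpatialAttention(rng)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        return ad.add(x, self.spatial(self.channel(x)))


class ConvBNMish(ad.Module):
    def __init__(self, rng, in_c: int, out_c: int):
        self.conv = ad.Conv2d(rng, in_c, out_c, 3, padding=1)
        self.bn = ad.BatchNorm2d(out_c)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        return ad.mish(self.bn(self.conv(x)))


class DecoderStage(ad.Module):
    """Bilinear x2 upsample, optional skip concat, two conv-BN-Mish blocks."""

    def __init__(self, rng, in_c: int, skip_c: int, out_c: int):
        self.block1 = ConvBNMish(rng, in_c + skip_c, out_c)
        self.block2 = ConvBNMish(rng, out_c, out_c)

    def forward(self, x: ad.Tensor, skip: ad.Tensor | None = None) -> ad.Tensor:
        x = ad.upsample_bilinear_2x(x)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip {skip.shape} does not match upsampled {x.shape}")
            x = ad.concat([x, skip], axis=1)
        return self.block2(self.block1(x))


class RefineHead(ad.Module):
    """Generation module G: two conv-BN-Mish blocks and a 1-channel conv."""

    def __init__(self, rng, dim: int):
        self.block1 = ConvBNMish(rng, dim, dim)
        self.block2 = ConvBNMish(rng, dim, dim)
        self.out = ad.Conv2d(rng, dim, 1, 3, padding=1)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        return self.out(self.block2(self.block1(x)))


class EncoderStage(ad.Module):
    """Alternating W/SW attention blocks followed by channel/spatial attention."""

    def __init__(self, rng, dim: int, cfg: ModelConfig, side: int, depth: int):
        self.blocks = [
            TransformerBlock(rng, dim, cfg.heads, cfg.window, side,
                             0 if b % 2 == 0 else cfg.window // 2, cfg.mlp_ratio)
            for b in range(depth)
        ]
        self.cbam = CBAM(rng, dim, cfg.cbam_reduction)

    def forward(self, tokens: ad.Tensor) -> ad.Tensor:
        """(B, H', W', C) tokens -> (B, C, H', W') attended spatial map."""
        for block in self.blocks:
            tokens = block(tokens)
        return self.cbam(ad.transpose(tokens, (0, 3, 1, 2)))


# -- the full network ------------------------------------------------------

class DosePredictionNet(ad.Module):
    """Four-stage windowed-attention encoder, conv decoder, refinement pyramid."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        side0 = cfg.grid_size // cfg.patch_size
        dims = cfg.stage_dims

        self.patch_embed = PatchEmbed(rng, cfg)
        self.stages = []
        self.mergers = []
        for i, dim in enumerate(dims):
            side = side0 // 2 ** i
            self.stages.append(EncoderStage(rng, dim, cfg, side, cfg.stage_depths[i]))
            if i < 3:
                self.mergers.append(PatchMerging(rng, dim))

        dc = cfg.decoder_channels
        # full-resolution stem: gives the last decoder stage a skip carrying
        # the input (CT + masks, notably the body contour) at native scale
        self.stem = ConvBNMish(rng, cfg.in_channels, dc[3])
        self.decoder = [
            DecoderStage(rng, dims[3], dims[2], dc[0]),
            DecoderStage(rng, dc[0], dims[1], dc[1]),
            DecoderStage(rng, dc[1], dims[0], dc[2]),
            DecoderStage(rng, dc[2], dc[3], dc[3]),
        ]
        self.heads_ = [RefineHead(rng, c) for c in dc]

    # encoder ------------------------------------------------------------
    def encode(self, x: ad.Tensor) -> list[ad.Tensor]:
        """Input (B, 33, n, n) -> per-stage NCHW feature maps (skips)."""
        t = self.patch_embed(x)
        features = []
        for i, stage in enumerate(self.stages):
            spatial = stage(t)                            # (B, C, H', W')
            features.append(spatial)
            t = ad.transpose(spatial, (0, 2, 3, 1))
            if i < 3:
                t = self.mergers[i](t)
        return features

    def refine_and_predict(self, decoder_features: list[ad.Tensor]) -> PredictionPyramid:
        """Generation heads + cumulative coarse-to-fine refinement."""
        phis = [head(f) for head, f in zip(self.heads_, decoder_features)]
        levels = [phis[0]]
        for phi in phis[1:]:
            levels.append(ad.add(phi, ad.upsample_bilinear_2x(levels[-1])))
        return PredictionPyramid(levels=levels, raw_maps=phis)

    def forward(self, x) -> PredictionPyramid:
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = ad.reshape(x, (1, *x.shape))
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels")
        if x.shape[2] != self.config.grid_size or x.shape[3] != self.config.grid_size:
            raise ValueError("input grid does not match the configured size")
        e1, e2, e3, e4 = self.encode(x)
        d1 = self.decoder[0](e4, e3)
        d2 = self.decoder[1](d1, e2)
        d3 = self.decoder[2](d2, e1)
        d4 = self.decoder[3](d3, self.stem(x))
        return self.refine_and_predict([d1, d2, d3, d4])
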