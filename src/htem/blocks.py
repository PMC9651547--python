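"""Building blocks of the hybrid transformer-CNN classifier.

The network mixes convolutional and attention machinery in four places:

* **CTE** (convolutional token embedding): conv 3x3 + batch norm + ReLU +
  max-pool, halving resolution and producing the first feature channels.
* **Feature embedding**: a 2x2 stride-2 convolution between stages that
  halves resolution and widens channels, yielding the stride-4/8/16/32
  hierarchy of feature maps.
* **CPSA** (convolutional parameter-sharing attention): multi-head attention
  whose key and value are one shared token matrix ``S`` obtained by a
  strided depthwise-separable projection of the input map.  The depthwise
  kernel size and stride ``s`` (the *reduction rate*) shrink ``S`` by a
  factor of ``s**2`` tokens, cutting attention cost accordingly, while the
  query keeps its full token count so output resolution is preserved.
* **LFFN** (local feed-forward network): the transformer feed-forward block
  recast as a sandglass of depthwise and pointwise convolutions on the
  2-D-reshaped tokens — depthwise k x k, pointwise 1x1 (C -> C), pointwise
  expand (C -> e*C), depthwise k x k, pointwise reduce (e*C -> C) — adding
  local spatial mixing that a plain two-layer FFN lacks.

Encoder blocks compose CPSA and LFFN with pre-layer-norm additive
residuals.  All feature maps are NHWC; token sequences are (B, N, C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


class ShapeError(ValueError):
    """An input violates a spatial/channel contract."""


class ConfigError(ValueError):
    """A configuration violates an architectural invariant."""


_ALLOWED_STRIDES = {1, 2, 4, 8, 16, 32}


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Batched NHWC feature map with its downsampling factor vs the input."""

    data: Tensor
    stride: int = 1

    def __post_init__(self):
        if not isinstance(self.data, Tensor):
            self.data = Tensor(np.asarray(self.data))
        if self.data.ndim != 4:
            raise ShapeError(f"FeatureMap needs rank-4 (B,H,W,C), got {self.data.shape}")
        b, h, w, c = self.data.shape
        if min(h, w, c) < 1:
            raise ShapeError(f"degenerate feature map shape {self.data.shape}")
        if self.stride not in _ALLOWED_STRIDES:
            raise ShapeError(f"stride tag {self.stride} not in {sorted(_ALLOWED_STRIDES)}")

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def channels(self) -> int:
        return self.data.shape[3]


@dataclass
class TokenSequence:
    """Batched (B, N, C) token sequence; ``spatial_side**2 == N`` when square."""

    data: Tensor
    spatial_side: int | None = None

    def __post_init__(self):
        if not isinstance(self.data, Tensor):
            self.data = Tensor(np.asarray(self.data))
        if self.data.ndim != 3:
            raise ShapeError(f"TokenSequence needs rank-3 (B,N,C), got {self.data.shape}")
        if self.data.shape[1] < 1:
            raise ShapeError("empty token sequence")
        if self.spatial_side is not None and self.spatial_side ** 2 != self.data.shape[1]:
            raise ShapeError(f"spatial_side {self.spatial_side} does not square to "
                             f"{self.data.shape[1]} tokens")

    @property
    def tokens(self) -> int:
        return self.data.shape[1]

    @property
    def channels(self) -> int:
        return self.data.shape[2]


def tokens_from_map(x: FeatureMap) -> TokenSequence:
    """Row-major flatten of an NHWC map to (B, H*W, C) tokens."""
    b, h, w, c = x.data.shape
    side = h if h == w else None
    return TokenSequence(ad.reshape(x.data, (b, h * w, c)), spatial_side=side)


def map_from_tokens(t: TokenSequence, spatial: tuple[int, int], stride: int = 1) -> FeatureMap:
    h, w = spatial
    b, n, c = t.data.shape
    if h * w != n:
        raise ShapeError(f"{h}x{w} spatial does not match {n} tokens")
    return FeatureMap(ad.reshape(t.data, (b, h, w, c)), stride=stride)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class CTEConfig:
    in_channels: int = 3
    out_channels: int = 16
    conv_kernel: int = 3
    pool_kernel: int = 3
    pool_stride: int = 2

    def __post_init__(self):
        if self.out_channels < 1:
            raise ConfigError("CTE out_channels must be >= 1")


@dataclass
class CPSAConfig:
    channels: int
    heads: int
    reduction_rate: int
    share_kv: bool = True
    project_q: bool = True

    def __post_init__(self):
        if self.channels % self.heads != 0:
            raise ConfigError(f"channels {self.channels} not divisible by heads {self.heads}")
        if self.reduction_rate < 1:
            raise ConfigError("reduction rate must be >= 1")

    @property
    def head_dim(self) -> int:
        return self.channels // self.heads


@dataclass
class LFFNConfig:
    channels: int
    expansion: int = 4
    kernel: int = 3
    use_ffn_baseline: bool = False

    def __post_init__(self):
        if self.expansion < 1:
            raise ConfigError("expansion ratio must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigError(f"LFFN kernel must be odd and >= 1, got {self.kernel}")


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class CTE(nn.Module):
    """Convolutional token embedding: conv(s=1) + BN + ReLU + maxpool(s=2)."""

    def __init__(self, cfg: CTEConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        pad = (cfg.conv_kernel - 1) // 2
        self.conv = nn.Conv2d(cfg.in_channels, cfg.out_channels,
                              cfg.conv_kernel, stride=1, padding=pad, rng=rng)
        self.bn = nn.BatchNorm2d(cfg.out_channels)

    def forward(self, x: FeatureMap) -> FeatureMap:
        if x.channels != self.cfg.in_channels:
            raise ShapeError(f"CTE expects {self.cfg.in_channels} channels, "
                             f"got {x.channels}")
        if x.height % 2 or x.width % 2:
            raise ShapeError(f"CTE needs even spatial sides, got {x.height}x{x.width}")
        h = self.conv(x.data)
        h = self.bn(h)
        h = ad.relu(h)
        pad = (self.cfg.pool_kernel - 1) // 2
        h = ad.maxpool2d(h, self.cfg.pool_kernel, self.cfg.pool_stride, pad)
        return FeatureMap(h, stride=x.stride * 2)


class FeatureEmbedding(nn.Module):
    """2x2 stride-2 convolution: halves resolution, widens channels."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.conv = nn.Conv2d(in_channels, out_channels, 2, stride=2, padding=0, rng=rng)

    def forward(self, x: FeatureMap) -> FeatureMap:
        if x.channels != self.in_channels:
            raise ShapeError(f"feature embedding expects {self.in_channels} channels, "
                             f"got {x.channels}")
        if x.height % 2 or x.width % 2:
            raise ShapeError(f"feature embedding needs even sides, got {x.height}x{x.width}")
        return FeatureMap(self.conv(x.data), stride=x.stride * 2)


class CPSA(nn.Module):
    """Convolutional parameter-sharing multi-head attention.

    The shared matrix ``S`` is a depthwise-separable projection of the input
    map: depthwise ``s x s`` stride ``s`` (adds only ``s**2 * C`` weights),
    then a pointwise 1x1 map which *is* the shared key/value projection.
    With ``share_kv=False`` the depthwise stays shared but the key and value
    get separate pointwise branches (one extra ``C**2 + C`` weights).
    """

    def __init__(self, cfg: CPSAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        s = cfg.reduction_rate
        c = cfg.channels
        self.dw = nn.DepthwiseConv2d(c, s, stride=s, padding=0, rng=rng)
        self.pw_shared = nn.Conv2d(c, c, 1, stride=1, padding=0, rng=rng)
        if not cfg.share_kv:
            self.pw_value = nn.Conv2d(c, c, 1, stride=1, padding=0, rng=rng)
        if cfg.project_q:
            self.q_proj = nn.Linear(c, c, rng)
        self.out_proj = nn.Linear(c, c, rng)

    # -- pieces ---------------------------------------------------------------
    def shared_projection(self, x: FeatureMap) -> TokenSequence:
        """Eq-style S: flatten(pointwise(depthwise(x, s, s)))."""
        s = self.cfg.reduction_rate
        if x.height % s or x.width % s:
            raise ShapeError(f"sides {x.height}x{x.width} not divisible by "
                             f"reduction rate {s}")
        h = self.dw(x.data)
        h = self.pw_shared(h)
        b, hh, ww, c = h.shape
        return TokenSequence(ad.reshape(h, (b, hh * ww, c)),
                             spatial_side=hh if hh == ww else None)

    def value_projection(self, x: FeatureMap) -> TokenSequence:
        """Separate value branch, only when parameter sharing is off."""
        s = self.cfg.reduction_rate
        if x.height % s or x.width % s:
            raise ShapeError(f"sides {x.height}x{x.width} not divisible by "
                             f"reduction rate {s}")
        h = self.pw_value(self.dw(x.data))
        b, hh, ww, c = h.shape
        return TokenSequence(ad.reshape(h, (b, hh * ww, c)),
                             spatial_side=hh if hh == ww else None)

    def attention(self, q: TokenSequence, k: TokenSequence,
                  v: TokenSequence | None = None) -> TokenSequence:
        """softmax(Q K^T / sqrt(d_head)) V per head, concat, linear mix.

        ``v`` defaults to ``k`` (the shared-matrix case of the model).
        """
        if v is None:
            v = k
        c = self.cfg.channels
        if q.channels != c or k.channels != c or v.channels != c:
            raise ShapeError(f"attention channel mismatch: q={q.channels}, "
                             f"k={k.channels}, v={v.channels}, expected {c}")
        nh, dh = self.cfg.heads, self.cfg.head_dim
        b, nq, _ = q.data.shape
        nk = k.tokens

        def split(t: Tensor, n: int) -> Tensor:
            t = ad.reshape(t, (b, n, nh, dh))
            return ad.transpose(t, (0, 2, 1, 3))     # (B, heads, N, d_head)

        q_in = self.q_proj(q.data) if self.cfg.project_q else q.data
        qh = split(q_in, nq)
        kh = split(k.data, nk)
        vh = split(v.data, nk)
        scores = ad.mul(ad.matmul(qh, ad.transpose(kh, (0, 1, 3, 2))),
                        1.0 / np.sqrt(dh))
        weights = ad.softmax(scores)                  # rows sum to 1
        ctx = ad.matmul(weights, vh)                  # (B, heads, Nq, d_head)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b, nq, c))
        return TokenSequence(self.out_proj(ctx), spatial_side=q.spatial_side)

    def forward(self, x: TokenSequence, spatial: tuple[int, int]) -> TokenSequence:
        fmap = map_from_tokens(x, spatial)
        s_tokens = self.shared_projection(fmap)
        v_tokens = None if self.cfg.share_kv else self.value_projection(fmap)
        out = self.attention(x, s_tokens, v_tokens)
        return TokenSequence(out.data, spatial_side=x.spatial_side)


class MHA(nn.Module):
    """Plain dense multi-head self-attention (ablation baseline)."""

    def __init__(self, cfg: CPSAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.q_proj = nn.Linear(c, c, rng)
        self.k_proj = nn.Linear(c, c, rng)
        self.v_proj = nn.Linear(c, c, rng)
        self.out_proj = nn.Linear(c, c, rng)

    def forward(self, x: TokenSequence, spatial: tuple[int, int]) -> TokenSequence:
        b, n, c = x.data.shape
        nh, dh = self.cfg.heads, self.cfg.head_dim

        def split(t):
            return ad.transpose(ad.reshape(t, (b, n, nh, dh)), (0, 2, 1, 3))

        qh = split(self.q_proj(x.data))
        kh = split(self.k_proj(x.data))
        vh = split(self.v_proj(x.data))
        scores = ad.mul(ad.matmul(qh, ad.transpose(kh, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        ctx = ad.matmul(ad.softmax(scores), vh)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b, n, c))
        return TokenSequence(self.out_proj(ctx), spatial_side=x.spatial_side)


class LFFN(nn.Module):
    """Local feed-forward network (sandglass of depthwise/pointwise convs).

    Pipeline on the 2-D-reshaped tokens: depthwise k x k -> pointwise 1x1
    (C -> C) -> pointwise expand (C -> e*C) -> GELU -> depthwise k x k ->
    pointwise reduce (e*C -> C) -> flatten.  Output shape equals input shape.
    """

    def __init__(self, cfg: LFFNConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, e, k = cfg.channels, cfg.expansion, cfg.kernel
        pad = (k - 1) // 2
        self.dw1 = nn.DepthwiseConv2d(c, k, stride=1, padding=pad, rng=rng)
        self.pw1 = nn.Conv2d(c, c, 1, stride=1, padding=0, rng=rng)
        self.expand = nn.Conv2d(c, e * c, 1, stride=1, padding=0, rng=rng)
        self.dw2 = nn.DepthwiseConv2d(e * c, k, stride=1, padding=pad, rng=rng)
        self.reduce = nn.Conv2d(e * c, c, 1, stride=1, padding=0, rng=rng)

    def forward(self, x: TokenSequence) -> TokenSequence:
        b, n, c = x.data.shape
        if c != self.cfg.channels:
            raise ShapeError(f"LFFN expects {self.cfg.channels} channels, got {c}")
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ShapeError(f"token count {n} is not a perfect square")
        h = ad.reshape(x.data, (b, side, side, c))
        h = self.dw1(h)
        h = self.pw1(h)
        h = ad.gelu(self.expand(h))
        h = self.dw2(h)
        h = self.reduce(h)
        return TokenSequence(ad.reshape(h, (b, n, c)), spatial_side=side)


class FFN(nn.Module):
    """Plain two-layer feed-forward block (ablation baseline)."""

    def __init__(self, cfg: LFFNConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, e = cfg.channels, cfg.expansion
        self.fc1 = nn.Linear(c, e * c, rng)
        self.fc2 = nn.Linear(e * c, c, rng)

    def forward(self, x: TokenSequence) -> TokenSequence:
        h = self.fc2(ad.gelu(self.fc1(x.data)))
        return TokenSequence(h, spatial_side=x.spatial_side)


class EncoderBlock(nn.Module):
    """Pre-norm residual composition of an attention and a feed-forward block.

    ``x <- x + attn(norm(x)); x <- x + ffn(norm(x))``; resolution preserved.
    """

    def __init__(self, cpsa_cfg: CPSAConfig, lffn_cfg: LFFNConfig,
                 rng: np.random.Generator,
                 attention_variant: str = "cpsa", ffn_variant: str = "lffn"):
        super().__init__()
        if attention_variant not in ("cpsa", "mha"):
            raise ConfigError(f"unknown attention variant {attention_variant!r}")
        if ffn_variant not in ("lffn", "ffn"):
            raise ConfigError(f"unknown ffn variant {ffn_variant!r}")
        c = cpsa_cfg.channels
        if lffn_cfg.channels != c:
            raise ConfigError("CPSA/LFFN channel mismatch")
        self.norm1 = nn.LayerNorm(c)
        self.attn = CPSA(cpsa_cfg, rng) if attention_variant == "cpsa" else MHA(cpsa_cfg, rng)
        self.norm2 = nn.LayerNorm(c)
        if ffn_variant == "lffn" and not lffn_cfg.use_ffn_baseline:
            self.ffn = LFFN(lffn_cfg, rng)
        else:
            self.ffn = FFN(lffn_cfg, rng)

    def forward(self, x: TokenSequence, spatial: tuple[int, int]) -> TokenSequence:
        h, w = spatial
        if h * w != x.tokens:
            raise ShapeError(f"spatial {h}x{w} does not match {x.tokens} tokens")
        normed = TokenSequence(self.norm1(x.data), spatial_side=x.spatial_side)
        attn_out = self.attn(normed, spatial)
        x = TokenSequence(ad.add(x.data, attn_out.data), spatial_side=x.spatial_side)
        normed = TokenSequence(self.norm2(x.data), spatial_side=x.spatial_side)
        ffn_out = self.ffn(normed)
        return TokenSequence(ad.add(x.data, ffn_out.data), spatial_side=x.spatial_side)


class ClassificationHead(nn.Module):
    """Global average pooling + layer norm + fully connected scores."""

    def __init__(self, channels: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        if num_classes < 2:
            raise ConfigError(f"need at least 2 classes, got {num_classes}")
        self.norm = nn.LayerNorm(channels)
        self.fc = nn.Linear(channels, num_classes, rng)
        self.num_classes = num_classes

    def forward(self, x: FeatureMap) -> Tensor:
        """Pre-softmax scores (B, num_classes)."""
        pooled = ad.mean(x.data, axis=(1, 2))        # (B, C)
        return self.fc(self.norm(pooled))

    def probabilities(self, x: FeatureMap) -> Tensor:
        return ad.softmax(self.forward(x))


class PositionEmbedding(nn.Module):
    """Learnable per-token offset added to stage-1 tokens (ablation only)."""

    def __init__(self, tokens: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.embed = nn.Parameter(nn.trunc_normal(rng, (1, tokens, channels)))

    def forward(self, x: TokenSequence) -> TokenSequence:
        if x.tokens != self.embed.shape[1]:
            raise ShapeError(f"position embedding built for {self.embed.shape[1]} "
                             f"tokens, got {x.tokens}")
        return TokenSequence(ad.add(x.data, self.embed), spatial_side=x.spatial_side)
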