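"""Assembly of the full hierarchical hybrid classifier.

The network is CTE -> [feature embedding -> depth x encoder block] x 4 ->
global-average-pool head.  The four stages run at strides 4/8/16/32 of the
input resolution with widening channels, giving CNN-style multi-scale
feature maps inside a transformer encoder.  No position embedding is used
by default; an optional learnable stage-1 embedding exists for ablation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor
from .blocks import (
    CTE, CTEConfig, ClassificationHead, ConfigError, CPSAConfig, EncoderBlock,
    FeatureEmbedding, FeatureMap, LFFNConfig, PositionEmbedding, ShapeError,
    map_from_tokens, tokens_from_map,
)

__all__ = [
    "StageSpec", "HTEMConfig", "ParameterCensus", "HTEM",
    "build_htem", "default_config", "count_parameters", "make_variant",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class StageSpec:
    depth: int
    channels: int
    heads: int
    reduction_rate: int
    expansion: int = 4
    kernel: int = 3

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError(f"stage depth must be >= 1, got {self.depth}")
        if self.channels % self.heads != 0:
            raise ConfigError(f"stage channels {self.channels} not divisible "
                              f"by heads {self.heads}")


@dataclass
class HTEMConfig:
    image_size: int = 224
    in_channels: int = 3
    cte: CTEConfig = field(default_factory=CTEConfig)
    stages: list[StageSpec] = field(default_factory=list)
    num_classes: int = 21
    use_position_embedding: bool = False
    attention_variant: str = "cpsa"
    ffn_variant: str = "lffn"

    def __post_init__(self):
        if self.image_size % 32 != 0:
            raise ConfigError(f"image_size must be divisible by 32, got {self.image_size}")
        if len(self.stages) != 4:
            raise ConfigError(f"exactly 4 stages required, got {len(self.stages)}")
        chans = [s.channels for s in self.stages]
        if any(a >= b for a, b in zip(chans, chans[1:])):
            raise ConfigError(f"stage channels must be strictly increasing, got {chans}")
        if self.num_classes < 2:
            raise ConfigError(f"need at least 2 classes, got {self.num_classes}")
        for i, st in enumerate(self.stages):
            side = self.image_size // (4 * 2 ** i)
            if side % st.reduction_rate:
                raise ConfigError(f"stage {i + 1} side {side} not divisible by "
                                  f"reduction rate {st.reduction_rate}")
        if self.cte.in_channels != self.in_channels:
            raise ConfigError("CTE in_channels must match config in_channels")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HTEMConfig":
        d = dict(d)
        d["cte"] = CTEConfig(**d["cte"])
        d["stages"] = [StageSpec(**s) for s in d["stages"]]
        return cls(**d)


def default_config(num_classes: int = 21, image_size: int = 224,
                   in_channels: int = 3) -> HTEMConfig:
    """Reference configuration: layout [2,2,4,2], channels 24/32/48/64,
    heads [1,2,4,8], reduction rates [8,4,2,1], expansion 4, kernel 3."""
    return HTEMConfig(
        image_size=image_size,
        in_channels=in_channels,
        cte=CTEConfig(in_channels=in_channels, out_channels=16),
        stages=[
            StageSpec(depth=2, channels=24, heads=1, reduction_rate=8),
            StageSpec(depth=2, channels=32, heads=2, reduction_rate=4),
            StageSpec(depth=4, channels=48, heads=4, reduction_rate=2),
            StageSpec(depth=2, channels=64, heads=8, reduction_rate=1),
        ],
        num_classes=num_classes,
    )


@dataclass
class ParameterCensus:
    entries: list[tuple[str, tuple[int, ...], int]]
    total_count: int
    serialized_megabytes: float

    def to_json(self) -> str:
        return json.dumps({
            "total_count": self.total_count,
            "serialized_megabytes": self.serialized_megabytes,
            "entries": [{"name": n, "shape": list(s), "count": c}
                        for n, s, c in self.entries],
        }, indent=2)

    def to_csv(self) -> str:
        lines = ["name,shape,count"]
        for n, s, c in self.entries:
            lines.append(f"{n},{'x'.join(map(str, s))},{c}")
        lines.append(f"TOTAL,,{self.total_count}")
        return "\n".join(lines)


class HTEM(nn.Module):
    """The hierarchical hybrid transformer-CNN classifier."""

    def __init__(self, cfg: HTEMConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.cte = CTE(cfg.cte, rng)
        embeddings = []
        stages = []
        in_ch = cfg.cte.out_channels
        for st in cfg.stages:
            embeddings.append(FeatureEmbedding(in_ch, st.channels, rng))
            blocks = []
            for _ in range(st.depth):
                cpsa_cfg = CPSAConfig(channels=st.channels, heads=st.heads,
                                      reduction_rate=st.reduction_rate)
                lffn_cfg = LFFNConfig(channels=st.channels, expansion=st.expansion,
                                      kernel=st.kernel)
                blocks.append(EncoderBlock(cpsa_cfg, lffn_cfg, rng,
                                           attention_variant=cfg.attention_variant,
                                           ffn_variant=cfg.ffn_variant))
            stages.append(blocks)
            in_ch = st.channels
        self.embeddings = embeddings
        self.stages = stages
        if cfg.use_position_embedding:
            side1 = cfg.image_size // 4
            self.pos_embed = PositionEmbedding(side1 * side1,
                                               cfg.stages[0].channels, rng)
        self.head = ClassificationHead(cfg.stages[3].channels, cfg.num_classes, rng)

    # -- inference -----------------------------------------------------------
    def forward(self, batch) -> Tensor:
        """Pre-softmax class scores (B, num_classes)."""
        if not isinstance(batch, FeatureMap):
            batch = FeatureMap(batch, stride=1)
        if batch.height != self.cfg.image_size or batch.width != self.cfg.image_size:
            raise ShapeError(f"expected {self.cfg.image_size}x{self.cfg.image_size} "
                             f"input, got {batch.height}x{batch.width}")
        x = self.cte(batch)
        for i, (embed, blocks) in enumerate(zip(self.embeddings, self.stages)):
            x = embed(x)
            spatial = (x.height, x.width)
            t = tokens_from_map(x)
            if i == 0 and self.cfg.use_position_embedding:
                t = self.pos_embed(t)
            for block in blocks:
                t = block(t, spatial)
            x = map_from_tokens(t, spatial, stride=x.stride)
        return self.head(x)

    def stage_shapes(self) -> list[tuple[int, int]]:
        """(side, channels) of each stage's feature map for the configured input."""
        return [(self.cfg.image_size // (4 * 2 ** i), st.channels)
                for i, st in enumerate(self.cfg.stages)]

    def predict_proba(self, batch) -> np.ndarray:
        from . import autodiff as ad
        return ad.softmax(self.forward(batch)).data

    def predict(self, batch) -> np.ndarray:
        """Argmax class per sample; ties resolve to the lowest class index."""
        return np.argmax(self.forward(batch).data, axis=1)


def build_htem(cfg: HTEMConfig, seed: int = 0) -> HTEM:
    return HTEM(cfg, seed=seed)


def count_parameters(model: nn.Module) -> ParameterCensus:
    """Census of every learnable weight, with 32-bit serialized size."""
    entries = []
    total = 0
    for name, p in model.named_parameters():
        cnt = int(np.prod(p.data.shape)) if p.data.shape else 1
        entries.append((name, tuple(p.data.shape), cnt))
        total += cnt
    return ParameterCensus(entries=entries, total_count=total,
                           serialized_megabytes=total * 4 / 2 ** 20)


def make_variant(base: HTEMConfig, seed: int = 0, *,
                 attention: str | None = None,
                 ffn: str | None = None,
                 position: bool | None = None,
                 layout: list[int] | None = None,
                 heads: list[int] | None = None,
                 reductions: list[int] | None = None,
                 kernel: int | None = None) -> HTEM:
    """Build an ablation variant of ``base`` with the requested substitutions."""
    stages = [dataclasses.replace(s) for s in base.stages]
    if layout is not None:
        if len(layout) != 4:
            raise ConfigError(f"layout must list 4 depths, got {layout}")
        for s, d in zip(stages, layout):
            s.depth = d
    if heads is not None:
        for s, h in zip(stages, heads):
            s.heads = h
    if reductions is not None:
        for s, r in zip(stages, reductions):
            s.reduction_rate = r
    if kernel is not None:
        for s in stages:
            s.kernel = kernel
    stages = [StageSpec(**dataclasses.asdict(s)) for s in stages]  # re-validate
    cfg = dataclasses.replace(
        base,
        stages=stages,
        attention_variant=attention if attention is not None else base.attention_variant,
        ffn_variant=ffn if ffn is not None else base.ffn_variant,
        use_position_embedding=position if position is not None else base.use_position_embedding,
    )
    return HTEM(cfg, seed=seed)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: HTEM, path) -> None:
    """Single-file archive: named float32 weight arrays + embedded config."""
    state = {k: v.astype(np.float32) for k, v in model.state_dict().items()}
    meta = json.dumps({"config": model.cfg.to_dict(), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path, expected_config: HTEMConfig | None = None) -> HTEM:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = HTEMConfig.from_dict(meta["config"])
    if expected_config is not None and expected_config.to_dict() != cfg.to_dict():
        raise ConfigError("checkpoint config does not match the expected config")
    model = HTEM(cfg, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model
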