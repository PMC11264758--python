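"""U-Net backbone and its attention-augmented variant.

The plain ``unet`` variant is a canonical 5-stage encoder/decoder with
double 3x3 convolutions, 2x2 max-pool downsampling, transposed-convolution
upsampling and skip concatenation.  The ``stc_unet`` variant keeps the same
backbone and inserts:

* an :class:`~stcunet.core_blocks.SKBlock` on the skip features of the three
  shallow stages (before concatenation into the decoder),
* a :class:`~stcunet.core_blocks.ViTBlock` on the stage-4 skip pathway and
  after the stage-5 (bottleneck) double convolution — the two deep stages,
* a :class:`~stcunet.core_blocks.CABlock` after each decoder double
  convolution.

The output is a single-channel logit map; its sigmoid is the per-pixel tumor
probability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor
from .core_blocks import CABlock, CAConfig, SKBlock, SKConfig, ViTBlock, ViTConfig

__all__ = [
    "ModelConfig",
    "SegmentationModel",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_VARIANTS = ("unet", "stc_unet")


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters.

    ``image_size`` fixes the spatial size the ViT positional embeddings are
    built for; the plain U-Net accepts any size divisible by 16.  Stage
    widths are ``base_width * (1, 2, 4, 8, 16)``.  ``vit_embed_dim`` of 0
    means "use the stage's channel count".
    """

    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 64
    image_size: int = 512
    sk_stages: frozenset = frozenset({1, 2, 3})
    vit_stages: frozenset = frozenset({4, 5})
    ca_in_decoder: bool = True
    upsample_mode: str = "transposed_conv"
    sk: SKConfig = field(default_factory=SKConfig)
    vit_embed_dim: int = 0
    vit_depth: int = 4
    vit_num_heads: int = 8
    vit_mlp_ratio: float = 2.0
    vit_dropout: float = 0.1
    ca: CAConfig = field(default_factory=CAConfig)

    def __post_init__(self):
        if self.base_width < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts and base_width must be positive")
        if self.image_size % 16:
            raise ValueError(f"image_size must be divisible by 16, got {self.image_size}")
        if not set(self.sk_stages) <= {1, 2, 3}:
            raise ValueError(f"sk_stages must be within {{1,2,3}}, got {set(self.sk_stages)}")
        if not set(self.vit_stages) <= {4, 5}:
            raise ValueError(f"vit_stages must be within {{4,5}}, got {set(self.vit_stages)}")
        if self.upsample_mode != "transposed_conv":
            raise ValueError("only transposed_conv upsampling is implemented")
        object.__setattr__(self, "sk_stages", frozenset(self.sk_stages))
        object.__setattr__(self, "vit_stages", frozenset(self.vit_stages))

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * m for m in (1, 2, 4, 8, 16))

    def vit_config(self, stage_channels: int) -> ViTConfig:
        return ViTConfig(
            embed_dim=self.vit_embed_dim or stage_channels,
            depth=self.vit_depth,
            num_heads=self.vit_num_heads,
            mlp_ratio=self.vit_mlp_ratio,
            dropout=self.vit_dropout,
        )

    # -- (de)serialization -------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sk_stages"] = sorted(self.sk_stages)
        d["vit_stages"] = sorted(self.vit_stages)
        d["sk"] = dataclasses.asdict(self.sk)
        d["ca"] = dataclasses.asdict(self.ca)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["sk_stages"] = frozenset(d["sk_stages"])
        d["vit_stages"] = frozenset(d["vit_stages"])
        sk = dict(d["sk"])
        sk["kernel_sizes"] = tuple(sk["kernel_sizes"])
        d["sk"] = SKConfig(**sk)
        d["ca"] = CAConfig(**d["ca"])
        return cls(**d)


class _DoubleConv(nn.Module):
    """(conv3x3 + BN + ReLU) x 2."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, rng, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, rng, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype),
            nn.ReLU(),
        )

    def forward(self, x):
        return self.body(x)


class SegmentationModel(nn.Module):
    """5-stage U-Net, optionally augmented with SK / ViT / CA blocks."""

    def __init__(self, cfg: ModelConfig, variant: str, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        if variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
        self.cfg = cfg
        self.variant = variant
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = cfg.stage_widths
        self.enc = nn.ModuleList([
            _DoubleConv(cfg.in_channels, w[0], rng, dtype),
            _DoubleConv(w[0], w[1], rng, dtype),
            _DoubleConv(w[1], w[2], rng, dtype),
            _DoubleConv(w[2], w[3], rng, dtype),
            _DoubleConv(w[3], w[4], rng, dtype),
        ])
        self.pool = nn.MaxPool2d()
        self.up = nn.ModuleList([
            nn.ConvTranspose2d(w[4], w[3], rng, dtype),
            nn.ConvTranspose2d(w[3], w[2], rng, dtype),
            nn.ConvTranspose2d(w[2], w[1], rng, dtype),
            nn.ConvTranspose2d(w[1], w[0], rng, dtype),
        ])
        self.dec = nn.ModuleList([
            _DoubleConv(w[4], w[3], rng, dtype),
            _DoubleConv(w[3], w[2], rng, dtype),
            _DoubleConv(w[2], w[1], rng, dtype),
            _DoubleConv(w[1], w[0], rng, dtype),
        ])
        self.head = nn.Conv2d(w[0], cfg.out_channels, 1, rng, dtype=dtype)

        augmented = variant == "stc_unet"
        self.sk_blocks = nn.ModuleList()
        self._sk_index: dict[int, int] = {}
        if augmented:
            for stage in sorted(cfg.sk_stages):
                self._sk_index[stage] = len(self.sk_blocks)
                self.sk_blocks.append(SKBlock(w[stage - 1], cfg.sk, rng, dtype))
        self.vit_blocks = nn.ModuleList()
        self._vit_index: dict[int, int] = {}
        if augmented:
            size = cfg.image_size
            for stage in sorted(cfg.vit_stages):
                ch = w[stage - 1]
                hw = size // (2 ** (stage - 1))
                self._vit_index[stage] = len(self.vit_blocks)
                self.vit_blocks.append(
                    ViTBlock(ch, hw, hw, cfg.vit_config(ch), rng, dtype))
        self.ca_blocks = nn.ModuleList()
        if augmented and cfg.ca_in_decoder:
            for stage in (4, 3, 2, 1):
                self.ca_blocks.append(CABlock(w[stage - 1], cfg.ca, rng, dtype))

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 4:
            raise ValueError(f"expected [B, C, H, W], got shape {x.shape}")
        _, _, h, w = x.shape
        if h % 16:
            raise ValueError(f"height {h} not divisible by 16")
        if w % 16:
            raise ValueError(f"width {w} not divisible by 16")
        if self._vit_index and (h != self.cfg.image_size or w != self.cfg.image_size):
            raise ValueError(
                f"this model's transformer stages are built for "
                f"{self.cfg.image_size}x{self.cfg.image_size} inputs, got {h}x{w}")

        skips = []
        cur = x
        for stage in range(1, 5):
            cur = self.enc[stage - 1](cur)
            skip = cur
            if stage in self._sk_index:
                skip = self.sk_blocks[self._sk_index[stage]](skip)
            if stage == 4 and 4 in self._vit_index:
                skip = self.vit_blocks[self._vit_index[4]](skip)
            skips.append(skip)
            cur = self.pool(cur)
        cur = self.enc[4](cur)
        if 5 in self._vit_index:
            cur = self.vit_blocks[self._vit_index[5]](cur)

        from .autodiff import concat
        for i, stage in enumerate((4, 3, 2, 1)):
            cur = self.up[i](cur)
            cur = concat([skips[stage - 1], cur], axis=1)
            cur = self.dec[i](cur)
            if len(self.ca_blocks):
                cur = self.ca_blocks[i](cur)
        return self.head(cur)


def build_model(cfg: ModelConfig, variant: str = "stc_unet", seed: int = 0,
                dtype=np.float32) -> SegmentationModel:
    """Build a seedably initialized ``unet`` or ``stc_unet`` model."""
    return SegmentationModel(cfg, variant, seed=seed, dtype=dtype)


def count_parameters(model: SegmentationModel) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: SegmentationModel, path, **metadata) -> None:
    """Write parameters + config + metadata into a single .npz archive."""
    meta = {"variant": model.variant, "seed": model.seed,
            "config": model.cfg.to_json(), **metadata}
    arrays = {"state/" + k: v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, dtype=np.float32) -> tuple[SegmentationModel, dict]:
    """Rebuild the model stored by :func:`save_checkpoint`."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("state/"):]: archive[k] for k in archive.files
                 if k.startswith("state/")}
    cfg = ModelConfig.from_json(meta["config"])
    model = SegmentationModel(cfg, meta["variant"], seed=int(meta.get("seed", 0)),
                              dtype=dtype)
    model.load_state_dict(state)
    return model, meta
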