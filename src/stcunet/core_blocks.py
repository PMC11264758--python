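"""The three attention blocks: selective kernel (SK), non-patch vision
transformer (ViT) and coordinate attention (CA).

Each block is a drop-in [C, H, W] -> [C, H, W] operator, with every sub-step
(split / fuse / select, embed / encoder layer, pool / gates) independently
callable so it can be tested against naive-loop oracles.

* **SK** runs the input through parallel convolution branches with kernel
  sizes 3, 5 and 7, pools the fused map into a compact descriptor, and mixes
  the branches with a per-channel softmax over branch logits — a learned,
  per-channel choice of receptive field.
* **ViT (non-patch)** treats every spatial position of a deep feature map as
  one token (sequence length H*W), adds a learned positional embedding and
  runs a standard pre-norm transformer encoder; tokens are finally projected
  back to the channel dimension and reassembled into the spatial map.
* **CA** pools each channel along height and along width separately, pushes
  the two directional profiles through a shared bottleneck, and derives two
  logistic gate vectors that rescale the map per (channel, row) and
  (channel, column), preserving positional information.

Blocks accept either a single [C, H, W] map or a batched [B, C, H, W] array
and return the same arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "SKConfig",
    "ViTConfig",
    "CAConfig",
    "DirectionalPooled",
    "FuseResult",
    "SKBlock",
    "ViTBlock",
    "CABlock",
    "ca_pool",
]


def _ensure_batched(x) -> tuple[Tensor, bool]:
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.ndim == 3:
        c, h, w = t.shape
        return t.reshape(1, c, h, w), True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"expected [C,H,W] or [B,C,H,W], got shape {t.shape}")


def _maybe_squeeze(t: Tensor, squeeze: bool) -> Tensor:
    if squeeze:
        return t.reshape(t.shape[1:])
    return t


def _check_spatial(t: Tensor) -> None:
    if t.shape[-1] < 1 or t.shape[-2] < 1:
        raise ValueError(f"spatial dimensions must be >= 1, got {t.shape}")


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SKConfig:
    """Selective-kernel settings: branch kernels and the fuse bottleneck.

    ``hidden_width(C) = max(C // reduction_ratio, min_hidden)`` is the width d
    of the compact descriptor z shared by all branch-logit heads.
    """

    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    reduction_ratio: int = 16
    min_hidden: int = 32

    def __post_init__(self):
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"SK kernel sizes must be odd positive, got {k}")
        if self.reduction_ratio < 1 or self.min_hidden < 1:
            raise ValueError("reduction_ratio and min_hidden must be positive")

    def hidden_width(self, channels: int) -> int:
        return max(channels // self.reduction_ratio, self.min_hidden, 1)


@dataclass(frozen=True)
class ViTConfig:
    """Non-patch transformer settings for one deep stage.

    ``embed_dim`` must be divisible by ``num_heads``.  The positional
    embedding has fixed length H*W (+1 with a class token) for the stage's
    configured spatial size; there is no interpolation to other sizes.
    """

    embed_dim: int = 512
    depth: int = 4
    num_heads: int = 8
    mlp_ratio: float = 2.0
    dropout: float = 0.1
    use_class_token: bool = False

    def __post_init__(self):
        if self.embed_dim < 1 or self.depth < 1 or self.num_heads < 1:
            raise ValueError("embed_dim, depth and num_heads must be positive")
        if self.embed_dim % self.num_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")


@dataclass(frozen=True)
class CAConfig:
    """Coordinate-attention settings.

    The shared bottleneck has width ``max(C // reduction_ratio, floor)``; the
    mid nonlinearity delta is hard-swish (or ReLU) and the gates are logistic.
    """

    reduction_ratio: int = 32
    nonlinearity: str = "hard_swish"
    floor: int = 8

    def __post_init__(self):
        if self.reduction_ratio < 1 or self.floor < 1:
            raise ValueError("reduction_ratio and floor must be positive")
        if self.nonlinearity not in ("hard_swish", "relu"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    def hidden_width(self, channels: int) -> int:
        return max(channels // self.reduction_ratio, self.floor, 1)


@dataclass
class DirectionalPooled:
    """Per-channel mean profiles along width (z_h: [.., C, H]) and height
    (z_w: [.., C, W])."""

    z_h: Tensor
    z_w: Tensor


@dataclass
class FuseResult:
    """SK fuse output: summed map u, its spatial mean s and the compact z."""

    u: Tensor
    pooled: Tensor
    z: Tensor


# ---------------------------------------------------------------------------
# selective kernel
# ---------------------------------------------------------------------------

class SKBlock(nn.Module):
    """Split / fuse / select over multi-size convolution branches."""

    def __init__(self, channels: int, cfg: SKConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.cfg = cfg or SKConfig()
        self.channels = channels
        rng = rng if rng is not None else np.random.default_rng(0)
        self.branches = nn.ModuleList(
            nn.Sequential(
                nn.Conv2d(channels, channels, k, rng, dtype=dtype),
                nn.BatchNorm2d(channels, dtype=dtype),
                nn.ReLU(),
            )
            for k in self.cfg.kernel_sizes
        )
        d = self.cfg.hidden_width(channels)
        self.fc_reduce = nn.Linear(channels, d, rng, dtype=dtype)
        self.fc_branch = nn.ModuleList(
            nn.Linear(d, channels, rng, dtype=dtype) for _ in self.cfg.kernel_sizes
        )

    # -- sub-steps ---------------------------------------------------------
    def split(self, x) -> list[Tensor]:
        """One convolution branch per kernel size; all outputs keep [C,H,W]."""
        xb, squeeze = _ensure_batched(x)
        _check_spatial(xb)
        return [_maybe_squeeze(br(xb), squeeze) for br in self.branches]

    def fuse(self, branches) -> FuseResult:
        """Sum the branches, average-pool per channel and compress to z."""
        batched = [_ensure_batched(b) for b in branches]
        shapes = {t.shape for t, _ in batched}
        if len(shapes) != 1:
            raise ValueError(f"branch shapes differ: {sorted(shapes)}")
        u = batched[0][0]
        for t, _ in batched[1:]:
            u = u + t
        s = u.mean(axis=(2, 3))  # [B, C]
        z = ad.relu(self.fc_reduce(s))  # [B, d]
        squeeze = batched[0][1]
        return FuseResult(u=_maybe_squeeze(u, squeeze), pooled=s, z=z)

    def select(self, branches, z: Tensor) -> tuple[Tensor, Tensor]:
        """Per-channel softmax over branch logits; convex-combine branches.

        Returns (v, weights) with weights of shape [B, n_branches, C] summing
        to 1 over the branch axis for every channel.
        """
        batched = [_ensure_batched(b) for b in branches]
        if len(batched) != len(self.fc_branch):
            raise ValueError(
                f"{len(batched)} branch maps but {len(self.fc_branch)} projections")
        if z.ndim == 1:
            z = z.reshape(1, -1)
        logits = ad.stack([fc(z) for fc in self.fc_branch], axis=1)  # [B, K, C]
        weights = ad.softmax(logits, axis=1)
        v = None
        b, _, c = weights.shape
        for k, (t, _) in enumerate(batched):
            wk = weights[:, k, :].reshape(b, c, 1, 1)
            term = t * wk
            v = term if v is None else v + term
        squeeze = batched[0][1]
        return _maybe_squeeze(v, squeeze), weights

    def forward(self, x) -> Tensor:
        branches = self.split(x)
        fused = self.fuse(branches)
        v, _ = self.select(branches, fused.z)
        return v


# ---------------------------------------------------------------------------
# non-patch vision transformer
# ---------------------------------------------------------------------------

class _EncoderLayer(nn.Module):
    """Pre-norm transformer encoder layer: MSA and MLP, each residual."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        d = cfg.embed_dim
        self.num_heads = cfg.num_heads
        self.head_dim = d // cfg.num_heads
        self.ln1 = nn.LayerNorm(d, dtype=dtype)
        self.qkv = nn.Linear(d, 3 * d, rng, init="trunc_normal", dtype=dtype)
        self.proj = nn.Linear(d, d, rng, init="trunc_normal", dtype=dtype)
        self.ln2 = nn.LayerNorm(d, dtype=dtype)
        hidden = int(round(cfg.mlp_ratio * d))
        self.mlp_in = nn.Linear(d, hidden, rng, init="trunc_normal", dtype=dtype)
        self.mlp_out = nn.Linear(hidden, d, rng, init="trunc_normal", dtype=dtype)
        self.drop = nn.Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31)))

    def _msa(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.num_heads, self.head_dim
        qkv = self.qkv(x)  # [B, N, 3D]
        qkv = qkv.reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)  # [3, B, h, N, hd]
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = ad.softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd)), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.drop(self.proj(out))

    def _mlp(self, x: Tensor) -> Tensor:
        return self.drop(self.mlp_out(ad.gelu(self.mlp_in(x))))

    def forward(self, z: Tensor) -> Tensor:
        z = self._msa(self.ln1(z)) + z
        z = self._mlp(self.ln2(z)) + z
        return z


class ViTBlock(nn.Module):
    """Transformer over one token per pixel of a fixed-size feature map.

    The incoming [C, H, W] map is flattened row-major (height, then width) to
    an H*W token sequence, linearly projected to ``cfg.embed_dim``, summed
    with a learned positional embedding, passed through ``cfg.depth`` encoder
    layers, layer-normalized and projected back to C channels at the original
    pixel positions, so the block preserves the map's shape.
    """

    def __init__(self, channels: int, height: int, width: int,
                 cfg: ViTConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.cfg = cfg or ViTConfig()
        self.channels = channels
        self.height = height
        self.width = width
        rng = rng if rng is not None else np.random.default_rng(0)
        d = self.cfg.embed_dim
        n = height * width + (1 if self.cfg.use_class_token else 0)
        self.proj_in = nn.Linear(channels, d, rng, init="trunc_normal", dtype=dtype)
        self.pos_embed = nn.Parameter(nn.trunc_normal(rng, (n, d), 0.02, dtype))
        if self.cfg.use_class_token:
            self.class_token = nn.Parameter(nn.trunc_normal(rng, (1, d), 0.02, dtype))
        else:
            self.class_token = None
        self.layers = nn.ModuleList(
            _EncoderLayer(self.cfg, rng, dtype=dtype) for _ in range(self.cfg.depth)
        )
        self.norm = nn.LayerNorm(d, dtype=dtype)
        self.proj_out = nn.Linear(d, channels, rng, init="trunc_normal", dtype=dtype)

    # -- sub-steps ---------------------------------------------------------
    def embed(self, x) -> Tensor:
        """Pixels -> tokens: row-major flatten, project to D, add positions."""
        xb, _ = _ensure_batched(x)
        b, c, h, w = xb.shape
        if (h, w) != (self.height, self.width):
            raise ValueError(
                f"positional embedding is fixed for {self.height}x{self.width}; "
                f"got {h}x{w} (no interpolation)")
        tokens = xb.transpose(0, 2, 3, 1).reshape(b, h * w, c)
        tokens = self.proj_in(tokens)
        if self.class_token is not None:
            cls = self.class_token.reshape(1, 1, -1)
            cls = cls * Tensor(np.ones((b, 1, 1), dtype=cls.dtype))
            tokens = ad.concat([cls, tokens], axis=1)
        return tokens + self.pos_embed

    def encoder_layer(self, z: Tensor, layer_index: int) -> Tensor:
        """Apply encoder layer ``layer_index`` (1-based, 1..depth)."""
        if not 1 <= layer_index <= len(self.layers):
            raise ValueError(f"layer_index {layer_index} out of 1..{len(self.layers)}")
        return self.layers[layer_index - 1](z)

    def readout(self, z: Tensor) -> Tensor:
        """Tokens -> map: drop class token, final LN, project D -> C, reshape."""
        if self.class_token is not None:
            z = z[:, 1:, :]
        z = self.proj_out(self.norm(z))
        b = z.shape[0]
        return z.reshape(b, self.height, self.width, self.channels).transpose(0, 3, 1, 2)

    def forward(self, x) -> Tensor:
        _, squeeze = _ensure_batched(x)
        z = self.embed(x)
        for layer in self.layers:
            z = layer(z)
        return _maybe_squeeze(self.readout(z), squeeze)


# ---------------------------------------------------------------------------
# coordinate attention
# ---------------------------------------------------------------------------

def ca_pool(x) -> DirectionalPooled:
    """Directional average pooling.

    z_h[c, h] = mean over width of row h; z_w[c, w] = mean over height of
    column w.  Accepts [C, H, W] or [B, C, H, W].
    """
    xb, squeeze = _ensure_batched(x)
    _check_spatial(xb)
    z_h = xb.mean(axis=3)  # [B, C, H]
    z_w = xb.mean(axis=2)  # [B, C, W]
    if squeeze:
        z_h = z_h.reshape(z_h.shape[1:])
        z_w = z_w.reshape(z_w.shape[1:])
    return DirectionalPooled(z_h=z_h, z_w=z_w)


class CABlock(nn.Module):
    """Coordinate attention: directional pooling -> shared bottleneck ->
    logistic row/column gates -> elementwise rescale of the input."""

    def __init__(self, channels: int, cfg: CAConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.cfg = cfg or CAConfig()
        self.channels = channels
        rng = rng if rng is not None else np.random.default_rng(0)
        d = self.cfg.hidden_width(channels)
        self.f1 = nn.Linear(channels, d, rng, dtype=dtype)
        self.f_h = nn.Linear(d, channels, rng, dtype=dtype)
        self.f_w = nn.Linear(d, channels, rng, dtype=dtype)

    def gates(self, pooled: DirectionalPooled) -> tuple[Tensor, Tensor]:
        """Shared 1x1 transform over the concatenated profiles, split, gate.

        Returns (g_h: [.., C, H], g_w: [.., C, W]) with entries in (0, 1).
        """
        z_h, z_w = pooled.z_h, pooled.z_w
        squeeze = z_h.ndim == 2
        if squeeze:
            z_h = z_h.reshape((1,) + z_h.shape)
            z_w = z_w.reshape((1,) + z_w.shape)
        h = z_h.shape[2]
        cat = ad.concat([z_h, z_w], axis=2)  # [B, C, H+W]
        t = cat.transpose(0, 2, 1)  # [B, H+W, C]
        f = self.f1(t)
        f = ad.hardswish(f) if self.cfg.nonlinearity == "hard_swish" else ad.relu(f)
        f_h, f_w = f[:, :h, :], f[:, h:, :]
        g_h = ad.sigmoid(self.f_h(f_h)).transpose(0, 2, 1)  # [B, C, H]
        g_w = ad.sigmoid(self.f_w(f_w)).transpose(0, 2, 1)  # [B, C, W]
        if squeeze:
            g_h = g_h.reshape(g_h.shape[1:])
            g_w = g_w.reshape(g_w.shape[1:])
        return g_h, g_w

    def forward(self, x) -> Tensor:
        xb, squeeze = _ensure_batched(x)
        pooled = ca_pool(xb)
        g_h, g_w = self.gates(pooled)
        b, c, h, w = xb.shape
        y = xb * g_h.reshape(b, c, h, 1) * g_w.reshape(b, c, 1, w)
        return _maybe_squeeze(y, squeeze)
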