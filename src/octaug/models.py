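"""Encoder-decoder segmentation models: U-Net and its variants.

Four architectures share a common vocabulary of blocks — two 3x3
convolutions with normalization and ReLU per stage, 2x2 max-pool
down-sampling, 2x2 transposed-convolution up-sampling:

* ``unet`` — plain skip connections between mirrored stages.
* ``unetpp`` — U-Net++: nested, dense skip pathways; the decoder node at
  level *i*, step *j* sees all previous same-level nodes plus the
  up-sampled node from the level below (no deep supervision).
* ``attention_unet`` — an additive attention gate on each skip connection,
  with the up-sampled coarser decoder feature as the gating signal.
* ``residual_unet`` — each stage is a residual module whose shortcut
  bypasses the two convolutions (1x1 projection when widths differ).

Depth (number of down-sampling stages) and base channel width are free so
that desk-scale instances (depth 2, a few channels, 64x64 inputs) exist
alongside the full-scale 512x512 preset of depth 4 / base 32.  All models
map a 1-channel image to 2-channel class logits at input resolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, concat

__all__ = ["ModelConfig", "build_model", "predict_mask", "ARCHITECTURES",
           "save_model", "load_model"]

ARCHITECTURES = ("unet", "unetpp", "attention_unet", "residual_unet")


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "unet"
    depth: int = 4
    base_channels: int = 32
    in_channels: int = 1
    out_classes: int = 2
    norm: str = "batch"  # "batch" | "instance" | "none"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {ARCHITECTURES}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")

    @staticmethod
    def desk(architecture: str = "unet", depth: int = 2, base_channels: int = 8
             ) -> "ModelConfig":
        """Small preset for CPU-scale experiments."""
        return ModelConfig(architecture, depth, base_channels)


def _norm_layer(kind: str, channels: int) -> nn.Module:
    if kind == "batch":
        return nn.BatchNorm2d(channels)
    if kind == "instance":
        return nn.InstanceNorm2d(channels)
    if kind == "none":
        return nn.Identity()
    raise ValueError(f"unknown norm {kind!r}")


class ConvBlock(nn.Module):
    """(conv 3x3 -> norm -> ReLU) twice."""

    def __init__(self, cin: int, cout: int, rng, norm: str):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.n1 = _norm_layer(norm, cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.n2 = _norm_layer(norm, cout)

    def forward(self, x: Tensor) -> Tensor:
        x = self.n1(self.conv1(x)).relu()
        return self.n2(self.conv2(x)).relu()


class ResBlock(nn.Module):
    """Residual module: shortcut bypasses the two convolutions."""

    def __init__(self, cin: int, cout: int, rng, norm: str):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.n1 = _norm_layer(norm, cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.n2 = _norm_layer(norm, cout)
        self.proj = nn.Conv2d(cin, cout, 1, rng) if cin != cout else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        h = self.n1(self.conv1(x)).relu()
        h = self.n2(self.conv2(h))
        return (h + self.proj(x)).relu()


class AttentionGate(nn.Module):
    """Additive attention on a skip connection.

    ``g`` (up-sampled coarser decoder feature) and ``x`` (encoder skip) are
    projected to an intermediate width, summed, squashed, and turned into a
    per-pixel gate in (0, 1) that multiplies the skip feature.
    """

    def __init__(self, channels: int, rng):
        super().__init__()
        inter = max(channels // 2, 1)
        self.wg = nn.Conv2d(channels, inter, 1, rng)
        self.wx = nn.Conv2d(channels, inter, 1, rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng)

    def forward(self, g: Tensor, x: Tensor) -> Tensor:
        a = (self.wg(g) + self.wx(x)).relu()
        gate = self.psi(a).sigmoid()
        return x * gate


class _UNetBase(nn.Module):
    def __init__(self, cfg: ModelConfig, rng, block_cls):
        super().__init__()
        self.cfg = cfg
        d, base = cfg.depth, cfg.base_channels
        ch = [base * 2**i for i in range(d + 1)]
        self.pool = nn.MaxPool2d()
        self.encoders = nn.ModuleList(
            [block_cls(cfg.in_channels if i == 0 else ch[i - 1], ch[i], rng, cfg.norm)
             for i in range(d)])
        self.bottleneck = block_cls(ch[d - 1], ch[d], rng, cfg.norm)
        self.ups = nn.ModuleList(
            [nn.ConvTranspose2d(ch[i + 1], ch[i], rng) for i in range(d)])
        self.decoders = nn.ModuleList(
            [block_cls(2 * ch[i], ch[i], rng, cfg.norm) for i in range(d)])
        self.head = nn.Conv2d(ch[0], cfg.out_classes, 1, rng)
        self.gates: nn.ModuleList | None = None

    def forward(self, x: Tensor) -> Tensor:
        self._check_input(x)
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for i in reversed(range(self.cfg.depth)):
            x = self.ups[i](x)
            skip = skips[i]
            if self.gates is not None:
                skip = self.gates[i](x, skip)
            x = self.decoders[i](concat([skip, x], axis=1))
        return self.head(x)

    def _check_input(self, x: Tensor):
        n, c, h, w = x.shape
        div = 2**self.cfg.depth
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channel(s), got {c}")
        if h % div or w % div:
            raise ValueError(f"spatial dims {h}x{w} not divisible by 2^depth = {div}")


class UNet(_UNetBase):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__(cfg, rng, ConvBlock)


class ResidualUNet(_UNetBase):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__(cfg, rng, ResBlock)


class AttentionUNet(_UNetBase):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__(cfg, rng, ConvBlock)
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self.gates = nn.ModuleList([AttentionGate(c, rng) for c in ch])


class UNetPlusPlus(nn.Module):
    """Nested dense decoder: node (i, j) aggregates nodes (i, 0..j-1) and
    the up-sampled node (i+1, j-1)."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.cfg = cfg
        d, base = cfg.depth, cfg.base_channels
        ch = [base * 2**i for i in range(d + 1)]
        self.pool = nn.MaxPool2d()
        self.backbone = nn.ModuleList(
            [ConvBlock(cfg.in_channels if i == 0 else ch[i - 1], ch[i], rng, cfg.norm)
             for i in range(d + 1)])
        self.nodes: dict[tuple[int, int], ConvBlock] = {}
        self.upconvs: dict[tuple[int, int], nn.ConvTranspose2d] = {}
        node_list, up_list = [], []
        for j in range(1, d + 1):
            for i in range(0, d + 1 - j):
                up = nn.ConvTranspose2d(ch[i + 1], ch[i], rng)
                blk = ConvBlock(j * ch[i] + ch[i], ch[i], rng, cfg.norm)
                self.upconvs[(i, j)] = up
                self.nodes[(i, j)] = blk
                up_list.append(up)
                node_list.append(blk)
        self._node_list = nn.ModuleList(node_list)
        self._up_list = nn.ModuleList(up_list)
        self.head = nn.Conv2d(ch[0], cfg.out_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        d = self.cfg.depth
        div = 2**d
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channel(s), got {c}")
        if h % div or w % div:
            raise ValueError(f"spatial dims {h}x{w} not divisible by 2^depth = {div}")
        grid: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i in range(d + 1):
            cur = self.backbone[i](cur if i == 0 else self.pool(grid[(i - 1, 0)]))
            grid[(i, 0)] = cur
        for j in range(1, d + 1):
            for i in range(0, d + 1 - j):
                up = self.upconvs[(i, j)](grid[(i + 1, j - 1)])
                feats = [grid[(i, jj)] for jj in range(j)] + [up]
                grid[(i, j)] = self.nodes[(i, j)](concat(feats, axis=1))
        return self.head(grid[(0, d)])


_BUILDERS = {
    "unet": UNet,
    "unetpp": UNetPlusPlus,
    "attention_unet": AttentionUNet,
    "residual_unet": ResidualUNet,
}


def build_model(config: ModelConfig, seed: int) -> nn.Module:
    """Instantiate an architecture with deterministic initialization."""
    rng = np.random.default_rng(seed)
    return _BUILDERS[config.architecture](config, rng)


def predict_mask(model: nn.Module, image: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (2, H, W) and argmax mask (H, W) for one image.

    The image must be (1, H, W) with intensities scaled to [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[0] != 1:
        raise ValueError("expected image of shape (1, H, W)")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0, 1]")
    was_training = model.training
    model.eval()
    logits = model(Tensor(image[None]))
    if was_training:
        model.train()
    probs = logits.log_softmax(axis=1).exp().data[0]
    return probs, probs.argmax(axis=0).astype(np.uint8)


def save_model(model: nn.Module, config: ModelConfig, path: str | Path):
    """Serialize parameters + architecture config to a ``.npz`` checkpoint."""
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(config)), **state)


def load_model(path: str | Path) -> tuple[nn.Module, ModelConfig]:
    with np.load(path, allow_pickle=False) as payload:
        config = ModelConfig(**json.loads(str(payload["__config__"])))
        model = build_model(config, seed=0)
        model.load_state_dict({k: payload[k] for k in payload.files
                               if k != "__config__"})
    return model, config
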