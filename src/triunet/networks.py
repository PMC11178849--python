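"""Brain-age network architectures.

Three regressors over skull-stripped T1-weighted volumes:

* :class:`TriUNet` — a 3D U-Net encoder-decoder whose skip connections pass
  through three-path "Trible Res Blocks" (identity / upsample-convolve-
  downsample / max-pool-residual-upsample, fused by channel concatenation),
  with a 3D ResNet-34 regression tail reading the full-resolution decoder
  output.
* :class:`UNet3D` — the same encoder-decoder without the Trible Res Blocks
  (the plain multi-scale baseline), same regression tail.
* :class:`ResNet34_3D` — a volumetric ResNet-34 (stage plan 3,4,6,3) with a
  configurable number of input channels, used directly on whole-brain or
  anatomical-region inputs, including multi-channel region stacks.

All networks output one scalar predicted age (years) per batch item. Feature
maps are channels-last ``(N, D, H, W, C)``. The final linear layer feeds an
affine calibration ``age = z * output_scale + output_offset`` whose defaults
center the output on the adult lifespan, so an untrained network already
predicts mid-range ages and the optimizer only has to learn the deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor


class ConfigurationError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_edge`` must be a cube edge divisible by ``2**depth`` and at least
    16. ``base_channels`` is the encoder width at full resolution (doubling
    per level), ``path_channels`` the width of each non-identity path of a
    Trible Res Block, and ``head_width`` the first-stage width of the
    ResNet-34 regression tail.
    """

    input_edge: int = 32
    in_channels: int = 1
    base_channels: int = 8
    depth: int = 3
    path_channels: int = 4
    head_width: int = 32
    norm_groups: int = 8
    output_offset: float = 53.5
    output_scale: float = 35.0
    seed: int = 0

    def __post_init__(self):
        if self.input_edge < 16:
            raise ConfigurationError(f"input_edge must be >= 16, got {self.input_edge}")
        if self.input_edge % (2 ** self.depth):
            raise ConfigurationError(
                f"input_edge {self.input_edge} not divisible by 2**depth = {2 ** self.depth}"
            )
        if self.in_channels < 1 or self.base_channels < 1 or self.path_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")

    @classmethod
    def for_edge(cls, edge: int, **kw) -> "NetworkConfig":
        """Defaults scaled to the input size (wider/deeper for large volumes)."""
        if edge >= 128:
            kw.setdefault("base_channels", 16)
            kw.setdefault("depth", 4)
            kw.setdefault("head_width", 64)
        return cls(input_edge=edge, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def conv_block(cin: int, cout: int, rng: np.random.Generator, groups: int = 8) -> nn.Sequential:
    """Convolution (3x3x3, padding 1) -> group norm -> ReLU; spatial size kept."""
    return nn.Sequential(nn.Conv3d(cin, cout, rng), nn.GroupNorm(cout, groups), nn.ReLU())


class BasicBlock(nn.Module):
    """Two conv_block stages plus an identity skip added to the output.

    When channel counts differ (or stride > 1) the skip is a 1x1x1 projection.
    With all convolution weights and biases at zero the block is exactly the
    identity map: each normalized-zero stage emits its (zero) shift, ReLU
    keeps it zero, and the sum returns the skip unchanged.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, groups: int = 8):
        super().__init__()
        self.stage1 = nn.Sequential(
            nn.Conv3d(cin, cout, rng, stride=stride), nn.GroupNorm(cout, groups), nn.ReLU()
        )
        self.stage2 = nn.Sequential(
            nn.Conv3d(cout, cout, rng), nn.GroupNorm(cout, groups), nn.ReLU()
        )
        if stride != 1 or cin != cout:
            self.proj = nn.Conv3d(cin, cout, rng, k=1, stride=stride, pad=0, bias=False)
        else:
            self.proj = None

    def forward(self, x):
        h = self.stage2(self.stage1(x))
        skip = x if self.proj is None else self.proj(x)
        return T.add(h, skip)


class TribleResBlock(nn.Module):
    """Three-path multi-scale fusion block.

    Path 1 passes the input through untouched; path 2 upsamples x2, applies
    two conv_blocks, then max-pools back down; path 3 max-pools, applies two
    basic blocks, then upsamples back up. The three aligned maps are
    concatenated on the channel axis, so output channels =
    ``in + 2 * path_channels`` at unchanged spatial size. Odd spatial sizes
    are rejected (no silent padding).
    """

    def __init__(self, cin: int, path_channels: int, rng: np.random.Generator, groups: int = 8):
        super().__init__()
        p = path_channels
        self.cin, self.path_channels = cin, p
        self.up_conv = nn.Sequential(conv_block(cin, p, rng, groups), conv_block(p, p, rng, groups))
        self.down_blocks = nn.Sequential(
            BasicBlock(cin, p, rng, groups=groups), BasicBlock(p, p, rng, groups=groups)
        )

    def forward(self, x):
        spatial = x.shape[1:4]
        if any(s % 2 for s in spatial) or min(spatial) < 4:
            raise ValueError(
                f"Trible Res Block requires even spatial dims >= 4, got {tuple(spatial)}"
            )
        p2 = F.maxpool2(self.up_conv(F.upsample2(x)))
        p3 = F.upsample2(self.down_blocks(F.maxpool2(x)))
        return T.concat([x, p2, p3], axis=-1)


class ResNet34_3D(nn.Module):
    """Volumetric ResNet-34 regression network.

    Stage plan 3,4,6,3 with widths ``w, 2w, 4w, 8w``; the stem uses a 7x7x7
    stride-2 convolution at edge >= 64 and a 3x3x3 stride-2 convolution below
    (small inputs would otherwise be dominated by the stem's receptive
    field). Five downsampling stages bring a 32-cube to a single voxel before
    global average pooling; spatial size saturates at 1 for smaller inputs.
    """

    MIN_EDGE = 16

    def __init__(self, in_channels: int = 1, input_edge: int = 128, width: int = 64,
                 groups: int = 8, output_offset: float = 53.5, output_scale: float = 35.0,
                 rng: np.random.Generator | None = None, seed: int = 0):
        super().__init__()
        if in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        if input_edge < self.MIN_EDGE:
            raise ConfigurationError(
                f"input_edge {input_edge} too small for the five downsampling stages; "
                f"minimum edge is {self.MIN_EDGE}"
            )
        rng = np.random.default_rng(seed) if rng is None else rng
        self.in_channels, self.input_edge = in_channels, input_edge
        self.output_offset, self.output_scale = output_offset, output_scale
        k = 7 if input_edge >= 64 else 3
        w = width
        self.stem = nn.Sequential(
            nn.Conv3d(in_channels, w, rng, k=k, stride=2), nn.GroupNorm(w, groups), nn.ReLU()
        )
        stages = []
        cin = w
        for stage_idx, (blocks, cout) in enumerate(zip((3, 4, 6, 3), (w, 2 * w, 4 * w, 8 * w))):
            for bi in range(blocks):
                stride = 2 if (stage_idx > 0 and bi == 0) else 1
                stages.append(BasicBlock(cin, cout, rng, stride=stride, groups=groups))
                cin = cout
        self.stages = nn.Sequential(*stages)
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(8 * w, 1, rng, std=0.01)

    def forward(self, x):
        h = self.stem(x)
        if min(h.shape[1:4]) >= 2 and all(s % 2 == 0 for s in h.shape[1:4]):
            h = F.maxpool2(h)
        h = self.stages(h)
        z = T.reshape(self.fc(self.pool(h)), (x.shape[0],))
        return T.scale_shift(z, self.output_scale, self.output_offset)


class _UNetCore(nn.Module):
    """Shared encoder-decoder; Trible Res Blocks on skips when enabled."""

    def __init__(self, cfg: NetworkConfig, trible: bool):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        g = cfg.norm_groups
        b, d, p = cfg.base_channels, cfg.depth, cfg.path_channels
        self.cfg, self.trible = cfg, trible
        chans = [b * 2 ** i for i in range(d + 1)]
        self.enc = []
        cin = cfg.in_channels
        for i in range(d):
            level = nn.Sequential(conv_block(cin, chans[i], rng, g), conv_block(chans[i], chans[i], rng, g))
            setattr(self, f"enc{i}", level)
            self.enc.append(level)
            cin = chans[i]
        self.bottleneck = nn.Sequential(
            conv_block(chans[d - 1], chans[d], rng, g), conv_block(chans[d], chans[d], rng, g)
        )
        self.skip_blocks = []
        for i in range(d):
            blk = TribleResBlock(chans[i], p, rng, g) if trible else None
            if blk is not None:
                setattr(self, f"trb{i}", blk)
            self.skip_blocks.append(blk)
        self.dec = []
        for i in reversed(range(d)):
            skip_ch = chans[i] + (2 * p if trible else 0)
            level = nn.Sequential(
                conv_block(chans[i + 1] + skip_ch, chans[i], rng, g),
                conv_block(chans[i], chans[i], rng, g),
            )
            setattr(self, f"dec{i}", level)
            self.dec.append(level)
        self.head = ResNet34_3D(
            in_channels=chans[0], input_edge=cfg.input_edge, width=cfg.head_width,
            groups=g, output_offset=cfg.output_offset, output_scale=cfg.output_scale, rng=rng,
        )

    def forward(self, x):
        skips = []
        h = x
        for level in self.enc:
            h = level(h)
            skips.append(h)
            h = F.maxpool2(h)
        h = self.bottleneck(h)
        for level, i in zip(self.dec, reversed(range(len(self.enc)))):
            h = F.upsample2(h)
            s = skips[i]
            if self.skip_blocks[i] is not None:
                s = self.skip_blocks[i](s)
            h = level(T.concat([h, s], axis=-1))
        return self.head(h)


class TriUNet(_UNetCore):
    """Tri-UNet: multi-scale U-Net with Trible Res Blocks and ResNet-34 tail."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__(cfg, trible=True)


class UNet3D(_UNetCore):
    """Plain 3D U-Net encoder-decoder with the same regression tail (baseline)."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__(cfg, trible=False)


def build_triunet(cfg: NetworkConfig) -> TriUNet:
    return TriUNet(cfg)


def build_unet3d_baseline(cfg: NetworkConfig) -> UNet3D:
    return UNet3D(cfg)


def build_resnet34_3d(in_channels: int, input_edge: int, **kw) -> ResNet34_3D:
    return ResNet34_3D(in_channels=in_channels, input_edge=input_edge, **kw)


def build_network(name: str, cfg: NetworkConfig):
    """Build a network by name: triunet, unet3d, or resnet34."""
    if name == "triunet":
        return build_triunet(cfg)
    if name == "unet3d":
        return build_unet3d_baseline(cfg)
    if name == "resnet34":
        return ResNet34_3D(
            in_channels=cfg.in_channels, input_edge=cfg.input_edge, width=cfg.head_width,
            groups=cfg.norm_groups, output_offset=cfg.output_offset,
            output_scale=cfg.output_scale, seed=cfg.seed,
        )
    raise ConfigurationError(f"unknown network '{name}' (expected triunet, unet3d or resnet34)")


def save_checkpoint(net: nn.Module, name: str, cfg: NetworkConfig, path) -> None:
    """Save weights as .npz with the architecture config and its hash embedded."""
    import hashlib
    import json
    from pathlib import Path

    meta = {"network": name, "config": cfg.to_dict()}
    blob = json.dumps(meta, sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(blob.encode(), dtype=np.uint8),
        __hash__=np.frombuffer(digest.encode(), dtype=np.uint8),
        **net.state_dict(),
    )


def load_checkpoint(path) -> tuple[nn.Module, str, NetworkConfig]:
    """Rebuild the network from a checkpoint; verifies the embedded config hash."""
    import hashlib
    import json

    with np.load(path) as data:
        blob = bytes(data["__meta__"].tobytes()).decode()
        digest = bytes(data["__hash__"].tobytes()).decode()
        if hashlib.sha256(blob.encode()).hexdigest() != digest:
            raise ValueError(f"checkpoint {path}: config hash mismatch (corrupt file?)")
        meta = json.loads(blob)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    cfg = NetworkConfig(**meta["config"])
    net = build_network(meta["network"], cfg)
    net.load_state_dict(state)
    return net, meta["network"], cfg


def predict_age(net: nn.Module, batch: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Evaluation-mode age prediction for a channels-last volume batch.

    ``batch``: (N, D, H, W, C) float array matching the network's configured
    input edge. Returns one finite scalar age (years) per item.
    """
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 4:
        batch = batch[..., None]
    edge = getattr(net, "input_edge", None) or net.cfg.input_edge
    cin = getattr(net, "in_channels", None) or net.cfg.in_channels
    if batch.shape[1:4] != (edge, edge, edge) or batch.shape[4] != cin:
        raise ValueError(
            f"input shape mismatch: expected (N, {edge}, {edge}, {edge}, {cin}), "
            f"received {batch.shape}"
        )
    preds = []
    with nn.no_grad():
        for i in range(0, batch.shape[0], batch_size):
            preds.append(net(Tensor(batch[i : i + batch_size])).data)
    return np.concatenate(preds)
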