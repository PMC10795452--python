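"""Spatial-temporal dual-path encoder-decoder with attention fusion.

Two structurally identical encoding paths with separate weights consume the
spatial triplet (three anatomically adjacent slices of one phase) and the
temporal triplet (the same slice in the previous/current/next phase), each
stacked as 3 input channels of a 2D network. Five encoding levels of
[3x3 conv - BN - ReLU] x2 with 2x2 max pooling between them bring a side-S
input to S/16 with 16x base channels at the bottleneck (for S=512, C=64:
32x32x1024 per path).

The bottleneck maps are fused CBAM-style: channel attention
``M_C = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F)))`` over the concatenated
32C channels with one shared MLP, then spatial attention
``M_S = sigmoid(conv7x7([avg_c(F'); max_c(F')]))``, each applied as a
multiplicative gate; a 1x1 convolution adjusts 32C back to 16C channels
before decoding. The single decoder upsamples four times, concatenating
skip connections from the spatial path only (the prediction target is the
center slice of the spatial triplet; temporal information reaches the
decoder through the fusion bottleneck), and ends in a 3x3 convolution to
one channel of raw logits.

A single-path five-slice U-Net with the same blocks serves both as the
comparator and as the liver-stage model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import TripletPair, normalize_hu
from .nn import autograd as ag
from .nn.layers import BatchNorm2d, Conv2d, ConvBNReLU, Linear, Module

__all__ = [
    "NetworkConfig",
    "EncoderPath",
    "ChannelAttention",
    "SpatialAttention",
    "FusionModule",
    "DualPathUNet",
    "BaselineUNet",
    "build_model",
    "shape_table",
    "save_checkpoint",
    "load_checkpoint",
]

DEPTH = 5  # encoding levels; four poolings -> downsample factor 16
DOWNSAMPLE = 2 ** (DEPTH - 1)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels=64`` reproduces the full-scale layer table; the MLP
    reduction ratio r=16 follows the CBAM convention, floored at 4 hidden
    units for desk-scale channel counts; the spatial-attention kernel is
    7x7.
    """

    base_channels: int = 64
    mlp_reduction: int = 16
    spatial_kernel: int = 7
    in_slices_per_path: int = 3
    out_channels: int = 1
    upsample: str = "bilinear"  # or "nearest"
    seed: int = 0

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels >= 1 required")
        if self.upsample not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")


def _check_extent(side):
    if side % DOWNSAMPLE:
        raise ValueError(
            f"input side {side} not divisible by {DOWNSAMPLE}; crop or pad the input"
        )


def _upsample(x, mode):
    return ag.upsample_bilinear2x(x) if mode == "bilinear" else ag.upsample_nearest2x(x)


class EncoderPath(Module):
    """One encoding path: five levels of double conv blocks, pooled between."""

    def __init__(self, in_ch, base, rng):
        super().__init__()
        widths = [base * 2**i for i in range(DEPTH)]
        self.blocks = []
        prev = in_ch
        for width in widths:
            self.blocks.append(ConvBNReLU(prev, width, rng))
            self.blocks.append(ConvBNReLU(width, width, rng))
            prev = width

    def __call__(self, x):
        """Return the five-level feature pyramid (index 4 = bottleneck)."""
        levels = []
        for i in range(DEPTH):
            if i > 0:
                x = ag.maxpool2x(x)
            x = self.blocks[2 * i](x)
            x = self.blocks[2 * i + 1](x)
            levels.append(x)
        return levels


class ChannelAttention(Module):
    """Channel gate over the concatenated spatial+temporal bottleneck.

    Global average- and max-pooling compress space; one shared two-layer
    MLP scores both vectors; their sum passes through a sigmoid to one
    weight per channel in (0, 1).
    """

    def __init__(self, channels, reduction, rng):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def _mlp(self, v):
        return self.fc2(ag.relu(self.fc1(v)))

    def __call__(self, f_s, f_t):
        fcat = ag.concat([f_s, f_t], axis=1)
        ap = self._mlp(ag.mean_spatial(fcat))
        mp = self._mlp(ag.amax_spatial(fcat))
        return ag.sigmoid(ag.add(ap, mp))


class SpatialAttention(Module):
    """Spatial gate: channel-wise avg/max pooling, one kxk conv, sigmoid."""

    def __init__(self, kernel, rng):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng)

    def __call__(self, f):
        pooled = ag.concat([ag.mean_channel(f), ag.amax_channel(f)], axis=1)
        return ag.sigmoid(self.conv(pooled))


class FusionModule(Module):
    """Sequential channel-then-spatial attention over the concatenated
    bottleneck maps, followed by a 1x1 channel-adjust convolution 32C -> 16C."""

    def __init__(self, bottleneck_channels, config, rng):
        super().__init__()
        self.channel_att = ChannelAttention(2 * bottleneck_channels, config.mlp_reduction, rng)
        self.spatial_att = SpatialAttention(config.spatial_kernel, rng)
        self.adjust = Conv2d(2 * bottleneck_channels, bottleneck_channels, 1, rng)

    def __call__(self, f_s, f_t, return_maps=False):
        f = ag.concat([f_s, f_t], axis=1)
        m_c = self.channel_att(f_s, f_t)
        n, c = m_c.shape
        f_prime = ag.mul(ag.reshape(m_c, (n, c, 1, 1)), f)
        m_s = self.spatial_att(f_prime)
        f_second = ag.mul(m_s, f_prime)
        fused = self.adjust(f_second)
        if return_maps:
            return fused, m_c, m_s, f_prime, f_second
        return fused


class _Decoder(Module):
    """Four [upsample x2 -> concat skip -> double conv] stages + output conv.

    Stage output widths follow the full-scale layer table: 16C at S/8, 8C
    at S/4, 4C at S/2, 2C at S, then a 3x3 convolution to one logit
    channel.
    """

    def __init__(self, base, out_channels, upsample_mode, rng):
        super().__init__()
        c = base
        out_widths = [16 * c, 8 * c, 4 * c, 2 * c]
        skip_widths = [8 * c, 4 * c, 2 * c, c]
        in_widths = [16 * c] + out_widths[:-1]
        self.stages = []
        for w_in, w_skip, w_out in zip(in_widths, skip_widths, out_widths):
            self.stages.append(ConvBNReLU(w_in + w_skip, w_out, rng))
            self.stages.append(ConvBNReLU(w_out, w_out, rng))
        self.out_conv = Conv2d(2 * c, out_channels, 3, rng)
        self.upsample_mode = upsample_mode

    def __call__(self, bottom, skips):
        x = bottom
        for i in range(4):
            x = _upsample(x, self.upsample_mode)
            x = ag.concat([x, skips[3 - i]], axis=1)
            x = self.stages[2 * i](x)
            x = self.stages[2 * i + 1](x)
        return self.out_conv(x)


class DualPathUNet(Module):
    """The full dual-path model: two encoders, attention fusion, one decoder."""

    arch = "dualpath"

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(self.config.seed)
        c = self.config.base_channels
        n_in = self.config.in_slices_per_path
        self.spatial_path = EncoderPath(n_in, c, rng)
        self.temporal_path = EncoderPath(n_in, c, rng)
        self.fusion = FusionModule(16 * c, self.config, rng)
        self.decoder = _Decoder(c, self.config.out_channels, self.config.upsample, rng)

    def __call__(self, x_spatial, x_temporal):
        """Logit map (N, 1, H, W) from (N, 3, H, W) triplet stacks."""
        for x in (x_spatial, x_temporal):
            shp = np.shape(x.data if isinstance(x, ag.Tensor) else x)
            _check_extent(shp[2])
            _check_extent(shp[3])
        spatial_levels = self.spatial_path(x_spatial)
        temporal_levels = self.temporal_path(x_temporal)
        fused = self.fusion(spatial_levels[-1], temporal_levels[-1])
        return self.decoder(fused, spatial_levels[:-1])

    def forward_pair(self, pair: TripletPair, window=None):
        """Run one normalized triplet pair; returns the (H, W) logit array."""
        kwargs = {} if window is None else {"window": window}
        x_s = normalize_hu(pair.spatial, **kwargs)[None]
        x_t = normalize_hu(pair.temporal, **kwargs)[None]
        return self(x_s, x_t).data[0, 0]


class BaselineUNet(Module):
    """Single-path five-slice U-Net comparator (and liver-stage model).

    Input channels stack {I_p^{k-1}, I_{p-1}^k, I_p^k, I_{p+1}^k, I_p^{k+1}};
    encoder and decoder blocks are identical to the dual-path model's, with
    skips from the single encoder.
    """

    arch = "baseline"

    def __init__(self, config: NetworkConfig | None = None, in_channels=5):
        super().__init__()
        self.config = config or NetworkConfig()
        self.in_channels = in_channels
        rng = np.random.default_rng(self.config.seed)
        c = self.config.base_channels
        self.encoder = EncoderPath(in_channels, c, rng)
        self.decoder = _Decoder(c, self.config.out_channels, self.config.upsample, rng)

    def __call__(self, x):
        shp = np.shape(x.data if isinstance(x, ag.Tensor) else x)
        _check_extent(shp[2])
        _check_extent(shp[3])
        levels = self.encoder(x)
        return self.decoder(levels[-1], levels[:-1])

    def forward_pair(self, pair: TripletPair, window=None):
        kwargs = {} if window is None else {"window": window}
        stack = np.stack(
            [
                pair.spatial[0],
                pair.temporal[0],
                pair.spatial[1],
                pair.temporal[2],
                pair.spatial[2],
            ]
        )
        return self(normalize_hu(stack, **kwargs)[None]).data[0, 0]


def build_model(arch: str, config: NetworkConfig | None = None) -> Module:
    if arch == "dualpath":
        return DualPathUNet(config)
    if arch == "baseline":
        return BaselineUNet(config)
    raise ValueError(f"unknown architecture {arch!r}")


def shape_table(config: NetworkConfig | None = None, input_side: int = 512):
    """Per-layer output sizes of the dual-path model, computed symbolically.

    Returns rows of ``(layer, kernel, output)`` matching the published
    layer-table layout, without instantiating any weights, so the
    full-scale 512x512 / 64-channel architecture can be checked in
    microseconds.
    """
    config = config or NetworkConfig()
    _check_extent(input_side)
    c, s = config.base_channels, input_side
    rows = [("Input", "", f"{s}x{s}x{config.in_slices_per_path}")]
    side = s
    for i in range(DEPTH):
        if i > 0:
            side //= 2
        width = c * 2**i
        rows.append((f"Conv_{i + 1}", "3x3", f"{side}x{side}x{width}"))
        rows.append((f"Conv_{i + 1}_1", "3x3", f"{side}x{side}x{width}"))
    bott = s // DOWNSAMPLE
    rows.append(("Fuse", f"{config.spatial_kernel}x{config.spatial_kernel}", f"{bott}x{bott}x{16 * c}"))
    side = bott
    for i, width in enumerate([16 * c, 8 * c, 4 * c, 2 * c]):
        side *= 2
        rows.append((f"Conv_{i + 6}", "3x3", f"{side}x{side}x{width}"))
    rows.append((f"Conv_10", "3x3", f"{side}x{side}x{config.out_channels}"))
    return rows


def format_shape_table(rows):
    width = max(len(r[0]) for r in rows)
    return "\n".join(f"{name:<{width}}  {kernel:<5} {out}" for name, kernel, out in rows)


# ---------------------------------------------------------------------------
# checkpoints (config embedded alongside the flat weight arrays)
# ---------------------------------------------------------------------------

def save_checkpoint(model, path):
    meta = {
        "arch": model.arch,
        "config": asdict(model.config),
        "in_channels": getattr(model, "in_channels", None),
    }
    state = model.state_dict()
    np.savez_compressed(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} does not exist")
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    config = NetworkConfig(**meta["config"])
    if meta["arch"] == "baseline":
        model = BaselineUNet(config, in_channels=meta.get("in_channels") or 5)
    else:
        model = DualPathUNet(config)
    model.load_state_dict(state)
    model.eval()
    return model
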