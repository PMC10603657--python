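"""The interactive segmentation network.

An encoder--decoder in the DeepLabv3+ family, extended for click guidance:

* the input is 5 channels (RGB plus the positive/negative click distance
  maps);
* the encoder is a backbone tapped at strides 2/4/8/16 (128, 256 and 728
  channels at the three skip levels) followed by atrous spatial pyramid
  pooling (ASPP) with dilation rates 1, 6, 12 and 18 and an image-level
  pooling branch;
* skip features are channel-reduced by 1x1 convolutions to 24/48/144;
* the decoder walks the pyramid layer by layer (16x -> 8x -> 4x -> 2x).
  At each fusion site two optional blocks modify the plain
  upsample-concatenate-convolve scheme:

  - **upsampling attention (UA)**: global average *and* max pooling of the
    high-level map, a shared two-layer bottleneck (Ch -> Ch/r -> Cl, r=16),
    matrix addition of the two transformed vectors and a sigmoid produce a
    per-channel weight vector that gates the low-level skip features;
  - **multi-head feature fusion (MHFF)**: the high- and low-level maps are
    mapped into a common 48-channel space by two *distinct* 3x3 kernels, the
    high-level map is upsampled 2x, both are concatenated (96 channels) and
    fused by a final 3x3 convolution back to 48 channels.

Both blocks can be toggled independently, giving the four ablation
configurations (baseline / +MHFF / +UA / both).

Two backbones share the same tap/channel contract: a deep aligned-Xception
style backbone with depthwise-separable residual blocks (the full model) and
a compact plain-convolution backbone for CPU-scale experiments.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .clicks import ClickSet, DEFAULT_TRUNCATION, encode_click_set
from .nn import Tensor
from .nn import autograd as ag

__all__ = [
    "NetworkConfig",
    "UpsamplingAttention",
    "MultiHeadFeatureFusion",
    "ASPP",
    "XceptionBackbone",
    "SimpleBackbone",
    "InteractiveSegModel",
    "build_model",
    "build_input",
    "predict_mask",
]


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters and ablation switches."""

    in_channels: int = 5
    skip_channels_raw: tuple[int, int, int] = (128, 256, 728)
    skip_channels_reduced: tuple[int, int, int] = (24, 48, 144)
    backbone_out_channels: int = 2048
    aspp_dilations: tuple[int, int, int, int] = (1, 6, 12, 18)
    aspp_out_channels: int = 256
    mhff_out_channels: int = 48
    ua_reduction: int = 16
    num_classes: int = 2
    use_mhff: bool = True
    use_ua: bool = True
    width_multiplier: float = 1.0
    backbone: str = "xception"  # "xception" | "simple"
    middle_blocks: int = 16
    normalize_inputs: bool = False

    def __post_init__(self):
        if any(
            red >= raw
            for red, raw in zip(self.skip_channels_reduced, self.skip_channels_raw)
        ):
            raise ValueError("reduced skip channels must be < raw skip channels")
        if self.ua_reduction < 1:
            raise ValueError("ua_reduction must be >= 1")
        if self.backbone not in ("xception", "simple"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    def ch(self, base: int) -> int:
        """Channel count after width scaling (always >= 1)."""
        return max(1, int(round(base * self.width_multiplier)))

    @classmethod
    def test_size(cls, **overrides) -> "NetworkConfig":
        """A width-reduced configuration practical on one CPU."""
        defaults = dict(width_multiplier=0.125, backbone="simple", middle_blocks=2)
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Decoder blocks


class UpsamplingAttention(nn.Module):
    """Squeeze-excitation-scale channel gating of skip features.

    Squeeze: global average and global max pooling of the high-level map give
    two 1x1xCh vectors. Excitation: both pass through a shared bottleneck
    (FC1: Ch -> Ch/r, ReLU, FC2: Ch/r -> Cl), are added and squashed by a
    sigmoid into a 1x1xCl weight vector. Scale: the low-level map is
    multiplied per channel by the weights.
    """

    def __init__(self, ch_high: int, ch_low: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, ch_high // reduction)
        self.ch_high = ch_high
        self.ch_low = ch_low
        self.fc1 = nn.Linear(ch_high, hidden, rng)
        self.fc2 = nn.Linear(hidden, ch_low, rng)

    def weight_vector(self, high: Tensor) -> Tensor:
        if high.shape[1] != self.ch_high:
            raise ValueError(
                f"UA expects {self.ch_high} high-level channels, got {high.shape[1]}"
            )
        pooled_avg = ag.global_avg_pool(high)
        pooled_max = ag.global_max_pool(high)
        z_avg = self.fc2(ag.relu(self.fc1(pooled_avg)))
        z_max = self.fc2(ag.relu(self.fc1(pooled_max)))
        return ag.sigmoid(ag.add(z_avg, z_max))  # (N, Cl)

    def forward(self, high: Tensor, low: Tensor) -> Tensor:
        if low.shape[1] != self.ch_low:
            raise ValueError(
                f"UA expects {self.ch_low} low-level channels, got {low.shape[1]}"
            )
        w = self.weight_vector(high)
        return ag.mul(low, _reshape4(w))


def _reshape4(x: Tensor) -> Tensor:
    """(N, C) -> (N, C, 1, 1), differentiable."""
    out_data = x.data[:, :, None, None]

    def backward(go):
        x._accumulate(go[:, :, 0, 0])

    return ag._node(out_data, (x,), backward)


class MultiHeadFeatureFusion(nn.Module):
    """Two-head feature-space mapping followed by fusion.

    Step 1: 3x3 convolution maps the high-level map to the fusion width.
    Step 2: a distinct 3x3 convolution maps the low-level map likewise.
    Step 3: the step-1 output is bilinearly upsampled 2x.
    Step 4: step-2 and step-3 outputs are concatenated.
    Step 5: a 3x3 convolution fuses the concatenation back to the fusion
    width. The block is exactly this five-step procedure (plain convolutions
    with bias); the decoder applies its nonlinearity after the block.
    """

    def __init__(
        self, ch_high: int, ch_low: int, out_channels: int, rng: np.random.Generator
    ):
        super().__init__()
        self.conv_high = nn.Conv2d(ch_high, out_channels, 3, rng, padding=1)
        self.conv_low = nn.Conv2d(ch_low, out_channels, 3, rng, padding=1)
        self.conv_fuse = nn.Conv2d(2 * out_channels, out_channels, 3, rng, padding=1)

    def forward(self, high: Tensor, low: Tensor) -> Tensor:
        lh, lw = low.shape[2], low.shape[3]
        if abs(lh - 2 * high.shape[2]) > 1 or abs(lw - 2 * high.shape[3]) > 1:
            raise ValueError(
                f"MHFF expects the low-level map at 2x the high-level size; "
                f"got high {high.shape[2:]}, low {low.shape[2:]}"
            )
        mapped_high = self.conv_high(high)  # step 1
        mapped_low = self.conv_low(low)  # step 2
        up_high = ag.resize_bilinear(mapped_high, lh, lw)  # step 3
        merged = ag.concat([mapped_low, up_high], axis=1)  # step 4
        return self.conv_fuse(merged)  # step 5


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: four dilated 3x3 branches + image pool."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        dilations: tuple[int, ...],
        rng: np.random.Generator,
    ):
        super().__init__()
        self.dilations = tuple(dilations)
        for i, d in enumerate(self.dilations):
            setattr(
                self,
                f"branch{i}",
                nn.ConvBNReLU(in_channels, out_channels, 3, rng, dilation=d),
            )
        self.pool_conv = nn.ConvBNReLU(in_channels, out_channels, 1, rng)
        n_branches = len(self.dilations) + 1
        self.project = nn.ConvBNReLU(n_branches * out_channels, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        outs = [self._children[f"branch{i}"](x) for i in range(len(self.dilations))]
        pooled = ag.global_avg_pool(x)  # (N, C)
        pooled = self.pool_conv(_reshape4(pooled))
        outs.append(ag.resize_bilinear(pooled, h, w))
        return self.project(ag.concat(outs, axis=1))


# ---------------------------------------------------------------------------
# Backbones


class _XceptionBlock(nn.Module):
    """Three separable convolutions with a (projected) residual connection."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        super().__init__()
        self.sep1 = nn.SeparableConvBNReLU(in_channels, out_channels, rng)
        self.sep2 = nn.SeparableConvBNReLU(out_channels, out_channels, rng)
        self.sep3 = nn.SeparableConvBNReLU(
            out_channels, out_channels, rng, stride=stride, relu=False
        )
        if stride != 1 or in_channels != out_channels:
            self.skip = nn.ConvBNReLU(
                in_channels, out_channels, 1, rng, stride=stride, relu=False
            )
        else:
            self.skip = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.sep3(self.sep2(self.sep1(x)))
        res = self.skip(x) if self.skip is not None else x
        return ag.relu(ag.add(y, res))


class XceptionBackbone(nn.Module):
    """Aligned-Xception style backbone with taps at strides 2/4/8/16.

    Entry flow reaches 128 channels at stride 2, 256 at stride 4 and 728 at
    stride 8; the middle flow repeats residual separable blocks at stride 16;
    the exit flow widens to 2048 channels for ASPP. The first convolution
    accepts the 5-channel click-augmented input.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        c = config.ch
        c2, c4, c8 = (c(x) for x in config.skip_channels_raw)
        self.out_channels = (c2, c4, c8, c(config.backbone_out_channels))
        self.conv1 = nn.ConvBNReLU(config.in_channels, c(64), 3, rng, stride=2)
        self.conv2 = nn.ConvBNReLU(c(64), c2, 3, rng)
        self.block_a = _XceptionBlock(c2, c4, rng, stride=2)
        self.block_b = _XceptionBlock(c4, c8, rng, stride=2)
        self.block_c = _XceptionBlock(c8, c8, rng, stride=2)
        for i in range(config.middle_blocks):
            setattr(self, f"middle{i}", _XceptionBlock(c8, c8, rng))
        self.n_middle = config.middle_blocks
        self.exit1 = nn.SeparableConvBNReLU(c8, c(1024), rng)
        self.exit2 = nn.SeparableConvBNReLU(c(1024), c(1536), rng)
        self.exit3 = nn.SeparableConvBNReLU(
            c(1536), c(config.backbone_out_channels), rng
        )

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        f2 = self.conv2(self.conv1(x))
        f4 = self.block_a(f2)
        f8 = self.block_b(f4)
        y = self.block_c(f8)
        for i in range(self.n_middle):
            y = self._children[f"middle{i}"](y)
        f16 = self.exit3(self.exit2(self.exit1(y)))
        return {"f2": f2, "f4": f4, "f8": f8, "f16": f16}


class SimpleBackbone(nn.Module):
    """Compact plain-convolution backbone honouring the same tap contract."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        c = config.ch
        c2, c4, c8 = (c(x) for x in config.skip_channels_raw)
        c16 = c(config.backbone_out_channels)
        self.out_channels = (c2, c4, c8, c16)
        self.stem = nn.ConvBNReLU(config.in_channels, c(64), 3, rng, stride=2)
        self.conv2 = nn.ConvBNReLU(c(64), c2, 3, rng)
        self.conv4 = nn.ConvBNReLU(c2, c4, 3, rng, stride=2)
        self.conv8 = nn.ConvBNReLU(c4, c8, 3, rng, stride=2)
        self.conv16 = nn.ConvBNReLU(c8, c16, 3, rng, stride=2)

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        f2 = self.conv2(self.stem(x))
        f4 = self.conv4(f2)
        f8 = self.conv8(f4)
        f16 = self.conv16(f8)
        return {"f2": f2, "f4": f4, "f8": f8, "f16": f16}


# ---------------------------------------------------------------------------
# Full model


class _FusionStage(nn.Module):
    """One decoder fusion site: optional UA gating, then MHFF or the plain
    upsample-concatenate-convolve fusion, always ending in a ReLU."""

    def __init__(
        self,
        ch_high: int,
        ch_low: int,
        out_channels: int,
        config: NetworkConfig,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.use_ua = config.use_ua
        self.use_mhff = config.use_mhff
        if self.use_ua:
            self.ua = UpsamplingAttention(ch_high, ch_low, config.ua_reduction, rng)
        if self.use_mhff:
            self.mhff = MultiHeadFeatureFusion(ch_high, ch_low, out_channels, rng)
        else:
            self.fuse = nn.ConvBNReLU(ch_high + ch_low, out_channels, 3, rng)

    def forward(self, high: Tensor, low: Tensor) -> Tensor:
        if self.use_ua:
            low = self.ua(high, low)
        if self.use_mhff:
            return ag.relu(self.mhff(high, low))
        up = ag.resize_bilinear(high, low.shape[2], low.shape[3])
        return self.fuse(ag.concat([up, low], axis=1))


class InteractiveSegModel(nn.Module):
    """Backbone -> ASPP -> layer-by-layer decoder -> 2-class logits."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        object.__setattr__(self, "config", config)
        rng = np.random.default_rng(seed)
        c = config.ch
        if config.backbone == "xception":
            self.backbone = XceptionBackbone(config, rng)
        else:
            self.backbone = SimpleBackbone(config, rng)
        red2, red4, red8 = (c(x) for x in config.skip_channels_reduced)
        self.reduce2 = nn.ConvBNReLU(self.backbone.out_channels[0], red2, 1, rng)
        self.reduce4 = nn.ConvBNReLU(self.backbone.out_channels[1], red4, 1, rng)
        self.reduce8 = nn.ConvBNReLU(self.backbone.out_channels[2], red8, 1, rng)
        aspp_out = c(config.aspp_out_channels)
        self.aspp = ASPP(
            self.backbone.out_channels[3], aspp_out, config.aspp_dilations, rng
        )
        dec = c(config.mhff_out_channels)
        self.stage8 = _FusionStage(aspp_out, red8, dec, config, rng)
        self.stage4 = _FusionStage(dec, red4, dec, config, rng)
        self.stage2 = _FusionStage(dec, red2, dec, config, rng)
        self.head_conv = nn.ConvBNReLU(dec, dec, 3, rng)
        self.classifier = nn.Conv2d(dec, config.num_classes, 1, rng)

    # --- pieces exposed for inspection and testing -------------------------

    def backbone_forward(self, x: Tensor) -> dict[str, Tensor]:
        h, w = x.shape[2], x.shape[3]
        for dim, name in ((h, "height"), (w, "width")):
            if dim % 16 != 0:
                raise ValueError(
                    f"input {name} {dim} is not divisible by 16; pad the input first"
                )
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        return self.backbone(x)

    def reduce_skips(self, pyramid: dict[str, Tensor]) -> dict[str, Tensor]:
        return {
            "f2": self.reduce2(pyramid["f2"]),
            "f4": self.reduce4(pyramid["f4"]),
            "f8": self.reduce8(pyramid["f8"]),
        }

    def aspp_forward(self, f16: Tensor) -> Tensor:
        return self.aspp(f16)

    def decoder_forward(self, context: Tensor, reduced: dict[str, Tensor]) -> Tensor:
        y = self.stage8(context, reduced["f8"])
        y = self.stage4(y, reduced["f4"])
        y = self.stage2(y, reduced["f2"])
        y = self.head_conv(y)
        logits = self.classifier(y)
        return ag.resize_bilinear(logits, 2 * logits.shape[2], 2 * logits.shape[3])

    def forward(self, x: Tensor) -> Tensor:
        pyramid = self.backbone_forward(x)
        context = self.aspp_forward(pyramid["f16"])
        reduced = self.reduce_skips(pyramid)
        return self.decoder_forward(context, reduced)


def build_model(config: NetworkConfig | None = None, seed: int = 0) -> InteractiveSegModel:
    return InteractiveSegModel(config or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Inference helpers


def build_input(
    image: np.ndarray,
    clicks: ClickSet,
    truncation: float = DEFAULT_TRUNCATION,
    normalize: bool = False,
) -> np.ndarray:
    """Stack image and click guidance maps into a (5, H, W) float array."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {image.shape}")
    h, w = image.shape[:2]
    d_pos, d_neg = encode_click_set(clicks, h, w, truncation)
    x = np.concatenate(
        [
            image.astype(np.float32).transpose(2, 0, 1),
            d_pos[None].astype(np.float32),
            d_neg[None].astype(np.float32),
        ],
        axis=0,
    )
    if normalize:
        x = x / np.float32(truncation)
    return x


def _pad_to_multiple(x: np.ndarray, multiple: int = 16) -> tuple[np.ndarray, int, int]:
    _, h, w = x.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)))
    return x, h, w


def predict_mask(
    model: InteractiveSegModel,
    image: np.ndarray,
    clicks: ClickSet,
    truncation: float = DEFAULT_TRUNCATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment one image given a click set.

    Returns ``(mask, probability)`` where mask is the argmax over the
    2-class softmax and probability is the per-pixel foreground probability,
    both at the original image size (bottom/right padding used to reach a
    /16 size is stripped).
    """
    x = build_input(image, clicks, truncation, normalize=model.config.normalize_inputs)
    x, h, w = _pad_to_multiple(x)
    model.eval()
    with nn.no_grad():
        logits = model(Tensor(x[None]))
    probs = ag.softmax2d(logits.data)[0, :, :h, :w]
    mask = (probs[1] > probs[0]).astype(np.uint8)
    return mask, probs[1]
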