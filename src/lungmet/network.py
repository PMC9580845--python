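"""Tailored U-Net 3+ for multiclass (background/lung/metastasis) slices.

The encoder has ``depth`` blocks starting at ``base_filters`` channels and
doubling per block (16, 32, 64, 128, 256 by default). Each block applies
(depthwise-separable 3x3 conv, batch norm, ReLU, dropout) twice; 2x2 max
pooling sits between blocks. The decoder uses full-scale skip connections:
every decoder stage gathers one feature map from each of the five scales —
all shallower encoder outputs, the same-scale deeper decoder output (or the
bridge), and all deeper decoder outputs — rescales each to the size of the
deeper decoder output (max pooling down, bilinear up), projects each to
``skip_channels_per_scale`` channels with a 3x3 conv + batch norm + ReLU,
and concatenates them: 5 scales x 32 channels = a 160-channel map. Each
decoder block then applies a 2x2/stride-2 transposed convolution (the 2x
upsampling step) followed by the same double separable-conv block as the
encoder. A 1x1 convolution and per-pixel softmax produce the 3-class
probability map. Deep supervision and classification guidance of the
original U-Net 3+ are not used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core_io import LabelStack, VolumeStack
from .layers import BatchNorm2d, Conv2d, Dropout, Module, SeparableConv2d

__all__ = [
    "NetworkSpec",
    "UNet3Plus",
    "build_network",
    "predict_stack",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "lungmet-checkpoint-v1"


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``skip_channels_per_scale * depth`` gives the width of the concatenated
    full-scale skip map entering each decoder block (160 by default).
    """

    in_channels: int = 1
    num_classes: int = 3
    depth: int = 5
    base_filters: int = 16
    skip_channels_per_scale: int = 32
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.depth < 2 or self.base_filters < 1:
            raise ValueError("need depth >= 2 and base_filters >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.in_channels < 1 or self.num_classes < 2:
            raise ValueError("need in_channels >= 1 and num_classes >= 2")

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2**i for i in range(self.depth))

    @property
    def skip_channels_total(self) -> int:
        return self.skip_channels_per_scale * self.depth

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.depth - 1)


class _ConvBlock(Module):
    """(separable conv 3x3, BN, ReLU, dropout) applied twice."""

    def __init__(self, in_ch, out_ch, dropout_rate, rng, drop_rng):
        super().__init__()
        self.conv1 = SeparableConv2d(in_ch, out_ch, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.drop1 = Dropout(dropout_rate, drop_rng)
        self.conv2 = SeparableConv2d(out_ch, out_ch, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.drop2 = Dropout(dropout_rate, drop_rng)

    def __call__(self, x):
        x = self.drop1(self.bn1(self.conv1(x)).relu())
        return self.drop2(self.bn2(self.conv2(x)).relu())


class _SkipBranch(Module):
    """Rescale a source map to the concatenation size, project to 32 ch."""

    def __init__(self, in_ch, out_ch, factor, direction, rng):
        super().__init__()
        self.factor = factor
        self.direction = direction  # 'down' | 'same' | 'up'
        self.proj = Conv2d(in_ch, out_ch, kernel=3, pad=1, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x):
        if self.direction == "down":
            x = ad.maxpool2d(x, self.factor)
        elif self.direction == "up":
            x = ad.resize_bilinear(x, self.factor)
        return self.bn(self.proj(x)).relu()


class _TConv(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        std = np.sqrt(2.0 / in_ch)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_ch, out_ch, 2, 2)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class _DecoderStage(Module):
    """Full-scale skip aggregation + 2x transposed conv + conv block."""

    def __init__(self, branches, cat_ch, out_ch, dropout_rate, rng, drop_rng):
        super().__init__()
        self.branches = branches  # list of _SkipBranch, one per source
        self.upsample = _TConv(cat_ch, out_ch, rng)
        self.block = _ConvBlock(out_ch, out_ch, dropout_rate, rng, drop_rng)
        self.last_concat_channels: int | None = None

    def __call__(self, sources):
        cat = ad.concat([b(s) for b, s in zip(self.branches, sources)], axis=1)
        self.last_concat_channels = cat.shape[1]
        return self.block(self.upsample(cat))


class UNet3Plus(Module):
    """The segmentation model; ``forward`` maps (N,1,H,W) to (N,3,H,W) probs."""

    def __init__(self, spec: NetworkSpec = NetworkSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(int(seed))
        self.drop_rng = np.random.default_rng(int(seed) + 1)
        widths = spec.encoder_widths
        d = spec.depth
        sc = spec.skip_channels_per_scale
        cat_ch = spec.skip_channels_total

        enc_in = (spec.in_channels,) + widths[:-1]
        self.encoders = [
            _ConvBlock(enc_in[i], widths[i], spec.dropout_rate, rng, self.drop_rng)
            for i in range(d)
        ]

        # decoder stages i = d-1 .. 1; stage i concatenates at scale i
        # (spatial size H / 2^i) and upsamples to scale i-1. Decoder outputs
        # all carry cat_ch channels.
        self.decoder_stages = []
        for i in range(d - 1, 0, -1):
            branches = []
            for k in range(1, i + 1):  # encoder sources E_k at scale k-1
                branches.append(
                    _SkipBranch(widths[k - 1], sc, 2 ** (i - k + 1), "down", rng)
                )
            for j in range(i + 1, d):  # deeper decoder outputs at scale j-1
                f = 2 ** (j - 1 - i)
                branches.append(
                    _SkipBranch(cat_ch, sc, f, "same" if f == 1 else "up", rng)
                )
            f = 2 ** (d - 1 - i)  # the bridge (deepest encoder) at scale d-1
            branches.append(
                _SkipBranch(widths[-1], sc, f, "same" if f == 1 else "up", rng)
            )
            self.decoder_stages.append(
                _DecoderStage(branches, cat_ch, cat_ch, spec.dropout_rate, rng, self.drop_rng)
            )
        self.head = Conv2d(cat_ch, spec.num_classes, kernel=1, pad=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        H, W = x.shape[2], x.shape[3]
        f = spec.downsample_factor
        if H % f or W % f:
            raise ValueError(
                f"input {H}x{W} must be divisible by 2^(depth-1) = {f}"
            )
        enc = []
        h = x
        for i, block in enumerate(self.encoders):
            if i > 0:
                h = ad.maxpool2d(h, 2)
            h = block(h)
            enc.append(h)
        bridge = enc[-1]

        dec_outputs: dict[int, Tensor] = {}  # stage index -> output
        for stage, i in zip(self.decoder_stages, range(spec.depth - 1, 0, -1)):
            sources = [enc[k - 1] for k in range(1, i + 1)]
            sources += [dec_outputs[j] for j in range(i + 1, spec.depth)]
            sources.append(bridge)
            dec_outputs[i] = stage(sources)
        logits = self.head(dec_outputs[1])
        return ad.softmax_channel(logits)

    __call__ = forward

    @property
    def decoder_concat_channels(self) -> list[int]:
        """Concatenated skip-map widths observed in the last forward pass."""
        return [s.last_concat_channels for s in self.decoder_stages]


def build_network(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> UNet3Plus:
    """Construct the model with seeded weight initialisation."""
    return UNet3Plus(spec, seed=seed)


def predict_stack(model: UNet3Plus, stack: VolumeStack, batch_size: int = 8) -> LabelStack:
    """Segment every slice of a stack independently.

    Slices go through the network in inference mode (dropout off, batch-norm
    running statistics); per-pixel argmax with lowest-class-index tie-break
    yields the multiclass mask.
    """
    model.eval()
    img = stack.normalized()
    Z = img.shape[0]
    out = np.zeros(img.shape, dtype=np.int64)
    with ad.no_grad():
        for lo in range(0, Z, batch_size):
            batch = img[lo : lo + batch_size][:, None, :, :]
            probs = model(Tensor(batch)).data
            out[lo : lo + batch_size] = probs.argmax(axis=1)
    return LabelStack(out, spacing_mm=stack.spacing_mm)


def save_checkpoint(model: UNet3Plus, path) -> None:
    """Single-file checkpoint: versioned header with the spec + weights."""
    header = {"format": CHECKPOINT_FORMAT, "spec": asdict(model.spec)}
    state = model.state_dict()
    np.savez(Path(path), __header__=json.dumps(header), **state)


def load_checkpoint(path) -> UNet3Plus:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["__header__"]))
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"{path}: unrecognised checkpoint format")
        model = UNet3Plus(NetworkSpec(**header["spec"]))
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__header__"})
    return model
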