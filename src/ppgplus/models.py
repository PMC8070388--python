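"""Backbone architectures and fine-tuning head adaptation.

The four backbones share one interface: AlexNet (8 learned layers), ResNet18
and ResNet34 (residual networks whose global-pool feature width is 512), and a
small CNN sized for CPU training on spectrogram images. Head adaptation follows
the fine-tuning recipe: for AlexNet the final 1000-way layer is removed and a
dropout plus fresh 4096 -> 2 layer appended; for the ResNets the final layer is
replaced by a fresh 512 -> 2 layer.

Pretrained ImageNet weights are not bundled; ``pretrained=True`` is accepted
for interface compatibility but falls back to seeded random initialization
with a warning, so the large backbones here support architecture accounting
and forward passes rather than transfer learning.

MAC counting convention: multiply-accumulates of convolution and affine layers
only (kernel size x output positions x channel fan); bias additions,
activations, pooling and normalization are excluded. Under this convention the
adapted AlexNet at 3 x 224 x 224 costs 0.71 GMAC and carries 57.01M trainable
parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import (
    AdaptiveAvgPool2d, AvgPool2d, BatchNorm2d, Conv2d, Dropout, Flatten,
    InputNorm, Linear, MaxPool2d, ReLU, Residual, Sequential, _layer_macs,
)

__all__ = [
    "ModelSpec",
    "BACKBONES",
    "adapt_backbone",
    "count_parameters",
    "count_macs",
    "NETWORK_INPUT_SHAPE",
]

NETWORK_INPUT_SHAPE = (3, 224, 224)


@dataclass(frozen=True)
class ModelSpec:
    """Backbone choice plus fine-tuning head configuration."""

    backbone: str = "small_cnn"
    dropout_p: float = 0.6
    n_outputs: int = 2
    pretrained: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_outputs < 2:
            raise ValueError("n_outputs must be >= 2")


def _alexnet_features(rng) -> list:
    return [
        Conv2d(3, 64, 11, stride=4, padding=2, rng=rng), ReLU(), MaxPool2d(3, 2),
        Conv2d(64, 192, 5, padding=2, rng=rng), ReLU(), MaxPool2d(3, 2),
        Conv2d(192, 384, 3, padding=1, rng=rng), ReLU(),
        Conv2d(384, 256, 3, padding=1, rng=rng), ReLU(),
        Conv2d(256, 256, 3, padding=1, rng=rng), ReLU(), MaxPool2d(3, 2),
        AdaptiveAvgPool2d(6), Flatten(),
    ]


def _alexnet(spec: ModelSpec, rng) -> Sequential:
    # classifier trunk kept; the 1000-way head is replaced by dropout + 4096 -> n_outputs
    return Sequential(
        _alexnet_features(rng)
        + [
            Dropout(0.5), Linear(9216, 4096, rng=rng), ReLU(),
            Dropout(0.5), Linear(4096, 4096, rng=rng), ReLU(),
            Dropout(spec.dropout_p), Linear(4096, spec.n_outputs, rng=rng),
        ]
    )


def _basic_block(in_ch, out_ch, stride, rng) -> Residual:
    main = Sequential([
        Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng),
        BatchNorm2d(out_ch), ReLU(),
        Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng),
        BatchNorm2d(out_ch),
    ])
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = Sequential([
            Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
            BatchNorm2d(out_ch),
        ])
    return Residual(main, shortcut)


def _resnet(spec: ModelSpec, blocks: tuple[int, int, int, int], rng) -> Sequential:
    layers: list = [
        Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        BatchNorm2d(64), ReLU(), MaxPool2d(3, 2),
    ]
    in_ch = 64
    for stage, (out_ch, n_blocks) in enumerate(zip((64, 128, 256, 512), blocks)):
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(_basic_block(in_ch, out_ch, stride, rng))
            in_ch = out_ch
    layers += [AdaptiveAvgPool2d(1), Flatten(), Linear(512, spec.n_outputs, rng=rng)]
    return Sequential(layers)


def _small_cnn(spec: ModelSpec, rng) -> Sequential:
    """Three conv blocks + two affine layers, preceded by per-sample input
    standardization and an 8x average-pool downsampler so a 224 x 224
    spectrogram trains in seconds on one CPU."""
    return Sequential([
        InputNorm(),
        AvgPool2d(8),                                              # 3 x 28 x 28
        Conv2d(3, 8, 3, padding=1, rng=rng), ReLU(), MaxPool2d(2),   # 8 x 14 x 14
        Conv2d(8, 16, 3, padding=1, rng=rng), ReLU(), MaxPool2d(2),  # 16 x 7 x 7
        Conv2d(16, 32, 3, padding=1, rng=rng), ReLU(), MaxPool2d(2), # 32 x 3 x 3
        Flatten(),
        Linear(32 * 3 * 3, 64, rng=rng), ReLU(),
        Dropout(spec.dropout_p),
        Linear(64, spec.n_outputs, rng=rng),
    ])


BACKBONES = {
    "alexnet": _alexnet,
    "resnet18": lambda spec, rng: _resnet(spec, (2, 2, 2, 2), rng),
    "resnet34": lambda spec, rng: _resnet(spec, (3, 4, 6, 3), rng),
    "small_cnn": _small_cnn,
}


def adapt_backbone(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Build the backbone with its fine-tuning head already in place."""
    if spec.backbone not in BACKBONES:
        raise ValueError(
            f"unknown backbone {spec.backbone!r}; choose from {sorted(BACKBONES)}"
        )
    if spec.pretrained:
        warnings.warn(
            "pretrained weights are not bundled; using seeded random initialization",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    return BACKBONES[spec.backbone](spec, rng)


def count_parameters(model: Sequential) -> int:
    """Total size of all trainable weight arrays."""
    return sum(p.size for p, _ in model.parameters())


def count_macs(model: Sequential, input_shape: tuple[int, int, int] = NETWORK_INPUT_SHAPE) -> int:
    """Analytic multiply-accumulate count for one forward pass (see module docstring)."""
    return _layer_macs(model, input_shape)
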