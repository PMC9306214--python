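"""U-Net architectures for nuclei masking: 2D and 3D variants.

Both variants have five encoder blocks (the fifth acting as the bottleneck)
and four decoder blocks.  Filter counts grow linearly: the kth encoder block
uses 28k filters in 2D and 16k in 3D, the kth decoder block 28(5-k) / 16(5-k),
which puts the two variants at nearly the same capacity (3.3 vs 3.2 million
parameters) and makes the 2D-versus-3D comparison a fair one.

Block internals (the filter rule, kernel sizes and the 3.3M/3.2M reference
capacities are fixed; the per-block layer count is the free choice that
realises them): encoder blocks at levels 1-4 and every decoder block stack six
3x3(x3) convolutions, each followed by ReLU; the bottleneck uses two;
upsampling is a x2 zero-stuffing transposed convolution with a 3x3(x3)
kernel acting on the in-plane axes; the output head is a per-voxel fully
connected layer, i.e. a 1x1(x1) convolution, with a sigmoid.  Pooling and
upsampling use 2x2 factors in 2D and 2x2x1 in 3D (the z axis is never
pooled).  This resolves to 3,285,241 trainable parameters in 2D and
3,216,769 in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Tuple

import numpy as np

from .engine import Conv, ReLU, Sequential, UNetGraph, ZeroStuffUp2

Variant = Literal["2D", "3D"]
TargetKind = Literal["M3D", "M3DE", "M2DE", "seeds"]

ENCODER_CONVS = 6
BOTTLENECK_CONVS = 2
DECODER_CONVS = 6

__all__ = ["UNetSpec", "TrainConfig", "build_unet", "build_network", "lr_at_epoch"]


@dataclass
class UNetSpec:
    variant: Variant
    target_kind: TargetKind = "M3D"
    n_encoders: int = 5
    n_decoders: int = 4
    filter_base: int = 0            # 28 (2D) or 16 (3D), filled in
    kernel: Tuple[int, ...] = ()
    pool_factors: Tuple[int, ...] = ()
    input_shape: Tuple[int, ...] = ()
    param_count: int = 0

    @property
    def encoder_filters(self) -> List[int]:
        return [self.filter_base * k for k in range(1, self.n_encoders + 1)]

    @property
    def decoder_filters(self) -> List[int]:
        return [self.filter_base * (self.n_encoders - k)
                for k in range(1, self.n_decoders + 1)]


@dataclass
class TrainConfig:
    """Training schedule: 200 epochs of Adam with a stepped learning rate."""

    epochs: int = 200
    batch_size: int = 4              # 16 for the 2D variant
    initial_lr: float = 1e-3
    rotation_fraction: float = 0.67  # axial rotations, uniform 0-360 deg
    mirror_fraction: float = 0.50
    boundary_weighting: bool = False # weighted-loss comparator only
    w0: float = 10.0
    sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.rotation_fraction, self.mirror_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation fractions must lie in [0, 1]")


def lr_at_epoch(epoch: int, initial_lr: float = 1e-3) -> float:
    """Stepped schedule: decayed by 5x after epoch 75 and 10x after epoch 110.

    Both decay factors are relative to the initial rate; epochs are 1-based.
    """
    if epoch <= 75:
        return initial_lr
    if epoch <= 110:
        return initial_lr / 5.0
    return initial_lr / 10.0


def build_network(variant: Variant, seed: int = 0) -> UNetGraph:
    """Instantiate the weights of one U-Net variant."""
    if variant not in ("2D", "3D"):
        raise ValueError(f"unknown variant {variant!r}")
    ndim = 2 if variant == "2D" else 3
    base = 28 if variant == "2D" else 16
    rng = np.random.default_rng(seed)
    enc_f = [base * k for k in range(1, 6)]
    dec_f = [base * (5 - k) for k in range(1, 5)]

    encoders = []
    cin = 1
    for level, f in enumerate(enc_f):
        n_convs = BOTTLENECK_CONVS if level == 4 else ENCODER_CONVS
        layers: List = []
        for _ in range(n_convs):
            layers += [Conv(cin, f, ndim, 3, rng), ReLU()]
            cin = f
        encoders.append(Sequential(layers))

    decoders = []
    for level, f in enumerate(dec_f):
        up = Sequential([ZeroStuffUp2(), Conv(cin, f, ndim, 3, rng), ReLU()])
        cin = f
        skip_f = enc_f[3 - level]
        layers = []
        c = cin + skip_f
        for _ in range(DECODER_CONVS):
            layers += [Conv(c, f, ndim, 3, rng), ReLU()]
            c = f
        decoders.append((up, Sequential(layers)))
        cin = f

    final = Conv(cin, 1, ndim, kernel=1, rng=rng)
    return UNetGraph(encoders, decoders, final)


def build_unet(variant: Variant, target_kind: TargetKind = "M3D") -> UNetSpec:
    """Resolve the full architecture description, including the parameter
    count of the instantiated network."""
    net = build_network(variant)
    if variant == "2D":
        spec = UNetSpec(variant="2D", target_kind=target_kind, filter_base=28,
                        kernel=(3, 3), pool_factors=(2, 2),
                        input_shape=(256, 256))
    else:
        spec = UNetSpec(variant="3D", target_kind=target_kind, filter_base=16,
                        kernel=(3, 3, 3), pool_factors=(2, 2, 1),
                        input_shape=(256, 256, 24))
    spec.param_count = net.n_parameters()
    return spec
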