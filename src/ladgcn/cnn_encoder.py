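"""Semantic branch: a VGG-style convolutional encoder of the whole tile.

Two variants share the same conv/ReLU/maxpool stage structure in which
every pooling halves the spatial map:

* ``vgg16``     — the 13-conv-layer VGG16 feature stack, fully connected
                  to a length-1024 semantic vector h_s (224 px input by
                  default; randomly initialized, no pretrained weights).
* ``vgg_small`` — a 4-conv desk-scale variant (64 px input, h_s of 64),
                  the default used throughout training and tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad

__all__ = ["CNNConfig", "CNNEncoder"]

_PLANS = {
    # entries: channel counts, "M" = 2x2 max pool
    "vgg16": (64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"),
    "vgg_small": (8, "M", 16, "M", 32, "M", 32, "M"),
}
_DEFAULTS = {"vgg16": (224, 1024), "vgg_small": (64, 64)}


@dataclasses.dataclass(frozen=True)
class CNNConfig:
    variant: str = "vgg_small"
    input_size: int | None = None
    out_dim: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.variant not in _PLANS:
            raise ValueError(f"unknown variant {self.variant!r}")
        size, dim = _DEFAULTS[self.variant]
        object.__setattr__(self, "input_size", self.input_size or size)
        object.__setattr__(self, "out_dim", self.out_dim or dim)
        n_pools = _PLANS[self.variant].count("M")
        if self.input_size % (2**n_pools):
            raise ValueError(f"input_size must be divisible by {2 ** n_pools}")
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")


class CNNEncoder:
    """Conv/ReLU/maxpool stages then a fully connected layer to h_s."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        plan = _PLANS[self.config.variant]
        rng = np.random.default_rng(self.config.seed)
        self.conv_w: list[ad.Tensor] = []
        self.conv_b: list[ad.Tensor] = []
        in_ch = 3
        size = self.config.input_size
        self.stage_sizes = [size]  # spatial size after each pooling stage
        for entry in plan:
            if entry == "M":
                size //= 2
                self.stage_sizes.append(size)
            else:
                self.conv_w.append(ad.parameter(ad.glorot_uniform(rng, (entry, in_ch, 3, 3))))
                self.conv_b.append(ad.parameter(np.zeros(entry)))
                in_ch = entry
        flat = in_ch * size * size
        self.fc_w = ad.parameter(ad.glorot_uniform(rng, (flat, self.config.out_dim)))
        self.fc_b = ad.parameter(np.zeros(self.config.out_dim))

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [*self.conv_w, *self.conv_b, self.fc_w, self.fc_b]

    def encode(self, images) -> ad.Tensor:
        """Map a (B, 3, H, W) batch to the (B, out_dim) semantic embedding."""
        x = images if isinstance(images, ad.Tensor) else ad.constant(images)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected (B, 3, {self.config.input_size}, {self.config.input_size}) input, got {x.shape}"
            )
        plan = _PLANS[self.config.variant]
        conv_idx = 0
        expected = self.config.input_size
        for entry in plan:
            if entry == "M":
                x = ad.maxpool2d(x)
                expected //= 2
                assert x.shape[2] == expected, "pooling must halve the spatial map"
            else:
                x = ad.relu(ad.conv2d(x, self.conv_w[conv_idx], self.conv_b[conv_idx]))
                conv_idx += 1
        x = ad.reshape(x, (x.shape[0], -1))
        return ad.linear(x, self.fc_w, self.fc_b)
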