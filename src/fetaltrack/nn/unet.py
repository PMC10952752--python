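"""A 3D U-Net for two-class (background / brain) voxel labelling.

Five encoder-decoder levels; each stage is two repeats of
(3x3x3 conv, instance norm, LeakyReLU).  Downsampling uses 2x2x2 average
pooling after the first two encoder stages and 2x2x2 max pooling after the
next two; the decoder mirrors the encoder with factor-2 trilinear upsampling,
channel-concatenation skip connections, and a final 1x1x1 convolution to the
class logits.
"""

from __future__ import annotations

import numpy as np

from . import layers as _layers
from .layers import (
    AvgPool3d,
    Conv3d,
    InstanceNorm3d,
    LeakyReLU,
    MaxPool3d,
    TrilinearUpsample,
)


class _ConvBlock:
    """(conv, norm, act) x2."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [
            Conv3d(c_in, c_out, 3, rng),
            InstanceNorm3d(c_out),
            LeakyReLU(),
            Conv3d(c_out, c_out, 3, rng),
            InstanceNorm3d(c_out),
            LeakyReLU(),
        ]

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class UNet3d:
    """See module docstring.  ``channels`` must be strictly increasing and of
    length 5 in the shipped configurations; the input edge must be divisible
    by ``2**(levels-1)``."""

    POOL_SCHEDULE = ("avg", "avg", "max", "max")

    def __init__(self, channels=(32, 64, 128, 256, 512), in_channels=1,
                 n_classes=2, seed=0):
        channels = tuple(int(c) for c in channels)
        if any(b <= a for a, b in zip(channels, channels[1:])):
            raise ValueError("channel widths must be strictly increasing")
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.in_channels = int(in_channels)
        self.n_classes = int(n_classes)
        self.levels = len(channels)
        self.enc = []
        c_prev = in_channels
        for c in channels:
            self.enc.append(_ConvBlock(c_prev, c, rng))
            c_prev = c
        self.pools = [
            AvgPool3d() if kind == "avg" else MaxPool3d()
            for kind in self.POOL_SCHEDULE[: self.levels - 1]
        ]
        self.ups = [TrilinearUpsample() for _ in range(self.levels - 1)]
        self.dec = [
            _ConvBlock(channels[i + 1] + channels[i], channels[i], rng)
            for i in range(self.levels - 2, -1, -1)
        ]
        self.head = Conv3d(channels[0], n_classes, kernel=1, rng=rng)

    # -- introspection ------------------------------------------------------
    def describe(self) -> dict:
        return {
            "levels": self.levels,
            "channels": self.channels,
            "conv_kernel": (3, 3, 3),
            "conv_stride": 1,
            "convs_per_stage": 2,
            "normalization": "instance",
            "activation": "leaky_relu",
            "pooling": list(self.POOL_SCHEDULE[: self.levels - 1]),
            "pool_size": (2, 2, 2),
            "upsampling": "trilinear",
            "skip_connections": "concatenation",
            "out_channels": self.n_classes,
        }

    def params(self):
        out = []
        for block in self.enc:
            out.extend(block.params())
        for block in self.dec:
            out.extend(block.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _check_input(self, x):
        if x.ndim != 4 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected ({self.in_channels}, X, Y, Z) input, got {x.shape}"
            )
        div = 2 ** (self.levels - 1)
        for e in x.shape[1:]:
            if e % div:
                raise ValueError(
                    f"input edge {e} not divisible by 2**(levels-1) = {div}"
                )

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a ``(in_channels, X, Y, Z)`` volume to class logits with the
        same spatial shape."""
        x = np.asarray(x, dtype=_layers.DTYPE)
        self._check_input(x)
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < self.levels - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = []
        for j, block in enumerate(self.dec):
            skip = skips.pop()
            x = self.ups[j].forward(x)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([x, skip], axis=0)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Backpropagate a logit gradient; accumulates parameter gradients and
        returns the input gradient."""
        g = self.head.backward(np.asarray(g, dtype=_layers.DTYPE))
        skip_grads = []
        for j in range(len(self.dec) - 1, -1, -1):
            g = self.dec[j].backward(g)
            n_skip = self._skip_channels[j]
            skip_grads.append(g[-n_skip:])
            g = self.ups[j].backward(g[:-n_skip])
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]  # skip_grads[k] holds the level-k grad
            g = self.enc[i].backward(g)
        return g

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> list:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=_layers.DTYPE)
            if a.shape != p.value.shape:
                raise ValueError("checkpoint does not match this architecture")
            p.value = a.copy()
            p.grad = np.zeros_like(p.value)
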