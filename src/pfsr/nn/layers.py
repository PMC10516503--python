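"""Building blocks of the reconstruction network.

Parameter containers follow the usual Module pattern: a module owns
parameters and sub-modules as attributes, and ``parameters()`` walks them in
construction order, which makes weight initialisation reproducible from a
single seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _kaiming_conv(rng: np.random.Generator, cout: int, cin: int, k: int, slope: float, dtype):
    """Kaiming fan-in initialisation matched to the leaky-ReLU gain."""
    fan_in = cin * k**3
    std = np.sqrt(2.0 / ((1.0 + slope**2) * fan_in))
    return rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(dtype)


class Conv3d(Module):
    def __init__(self, cin, cout, *, k=3, stride=1, slope=0.1, rng=None,
                 zero_init=False, dtype=np.float32):
        self.stride = stride
        if zero_init:
            self.weight = Parameter(np.zeros((cout, cin, k, k, k), dtype=dtype))
        else:
            self.weight = Parameter(_kaiming_conv(rng, cout, cin, k, slope, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias, stride=self.stride)


class ChannelAttention(Module):
    """Per-channel sigmoid gates from a squeeze-and-excite bottleneck.

    Global spatial average -> 1x1x1 conv down to the attention bottleneck ->
    leaky ReLU -> 1x1x1 conv back up -> sigmoid; the input is rescaled
    channel-wise by the resulting gates in (0, 1).
    """

    def __init__(self, channels, attention_channels, *, slope=0.1, rng=None, dtype=np.float32):
        self.slope = slope
        self.squeeze = Conv3d(channels, attention_channels, k=1, slope=slope, rng=rng, dtype=dtype)
        self.excite = Conv3d(attention_channels, channels, k=1, slope=slope, rng=rng, dtype=dtype)

    def gates(self, x: Tensor) -> Tensor:
        s = ag.spatial_mean(x)
        h = ag.leaky_relu(self.squeeze(s), self.slope)
        return ag.sigmoid(self.excite(h))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.mul(x, self.gates(x))


class SpatialAttention(Module):
    """A single-channel sigmoid gate map from channel-pooled statistics.

    Mean- and max-pooling over channels are concatenated (2 channels), passed
    through one 3³ convolution and a sigmoid; the same gate map multiplies
    every channel.
    """

    def __init__(self, *, slope=0.1, rng=None, dtype=np.float32):
        self.conv = Conv3d(2, 1, k=3, slope=slope, rng=rng, dtype=dtype)

    def gates(self, x: Tensor) -> Tensor:
        pooled = ag.concat_channels([ag.channel_mean(x), ag.channel_max(x)])
        return ag.sigmoid(self.conv(pooled))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.mul(x, self.gates(x))


class MRCAB(Module):
    """Modified residual channel-attention block: conv-LReLU-conv-CA + skip."""

    def __init__(self, channels, attention_channels, *, slope=0.1, rng=None, dtype=np.float32):
        self.slope = slope
        self.conv1 = Conv3d(channels, channels, slope=slope, rng=rng, dtype=dtype)
        self.conv2 = Conv3d(channels, channels, slope=slope, rng=rng, dtype=dtype)
        self.ca = ChannelAttention(channels, attention_channels, slope=slope, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv2(ag.leaky_relu(self.conv1(x), self.slope))
        return ag.add(x, self.ca(y))


class ResidualGroup(Module):
    """A cascade of mRCABs plus a trailing conv, wrapped in a group residual."""

    def __init__(self, channels, attention_channels, n_blocks, *, slope=0.1, rng=None, dtype=np.float32):
        self.blocks = [
            MRCAB(channels, attention_channels, slope=slope, rng=rng, dtype=dtype)
            for _ in range(n_blocks)
        ]
        self.tail = Conv3d(channels, channels, slope=slope, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        y = x
        for blk in self.blocks:
            y = blk(y)
        return ag.add(x, self.tail(y))


class MultiscaleExtractor(Module):
    """Three-level feature pyramid with channel attention per scale.

    Features are downsampled twice by stride-2 convolutions; each level is
    refined by a conv + channel attention; coarser levels are brought back up
    with trilinear 2x interpolation and added as skip connections, so high
    frequencies lost during downsampling are retained.
    """

    def __init__(self, channels, attention_channels, n_scales=3, *, slope=0.1, rng=None, dtype=np.float32):
        self.slope = slope
        self.n_scales = n_scales
        self.downs = [
            Conv3d(channels, channels, stride=2, slope=slope, rng=rng, dtype=dtype)
            for _ in range(n_scales - 1)
        ]
        self.convs = [
            Conv3d(channels, channels, slope=slope, rng=rng, dtype=dtype) for _ in range(n_scales)
        ]
        self.cas = [
            ChannelAttention(channels, attention_channels, slope=slope, rng=rng, dtype=dtype)
            for _ in range(n_scales)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        levels = [x]
        for down in self.downs:
            levels.append(ag.leaky_relu(down(levels[-1]), self.slope))
        feats = [
            ca(ag.leaky_relu(conv(lvl), self.slope))
            for lvl, conv, ca in zip(levels, self.convs, self.cas)
        ]
        out = feats[-1]
        for finer in reversed(feats[:-1]):
            out = ag.add(finer, ag.upsample_trilinear2(out))
        return out
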