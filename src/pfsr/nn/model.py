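"""The PF-SR 3D super-resolution reconstruction network.

The network maps a low-resolution, partial-Fourier-sampled, noisy volume in
[0, 1] to a 2x-super-resolved volume by learning the *residue* between the
high-resolution image and the trilinearly upsampled input:

    shallow 3³ conv
      -> multiscale feature extraction (stride-2 pyramid + channel attention)
      -> multiscale spatial attention
      -> cascade of residual groups (each: 5 mRCABs + conv, group residual)
      -> subpixel convolution (3D pixel shuffle, 2x per axis)
      -> final 1-channel conv producing the residue
    output = residue + trilinear 2x upsample of the input

Every convolution uses 3x3x3 kernels (1x1x1 inside the channel-attention
bottleneck), 64 feature channels at paper scale, and leaky-ReLU activations
of slope 0.1.  The residual-group count defaults to 23, which puts the total
parameter count at 29,567,400 (~29.6 M); see docs/methods.md for the
arithmetic.  The final residue conv is zero-initialised, so an untrained
model reproduces trilinear interpolation exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..grid import VolumeGrid
from . import autograd as ag
from .autograd import Tensor, no_grad
from .layers import Conv3d, Module, MultiscaleExtractor, ResidualGroup, SpatialAttention

#: residual-group count that realises the ~29.7 M parameter budget
PAPER_N_RG = 23


@dataclass(frozen=True)
class ModelConfig:
    """Complete architecture description; the model is reconstructible from it alone."""

    n_rg: int = PAPER_N_RG
    n_mrcab_per_rg: int = 5
    channels: int = 64
    attention_channels: int = 8
    kernel: int = 3
    lrelu_slope: float = 0.1
    upscale: int = 2
    n_scales: int = 3

    def validate(self) -> None:
        problems = []
        if self.n_rg < 1:
            problems.append(f"n_rg={self.n_rg} (must be >= 1)")
        if self.n_mrcab_per_rg < 1:
            problems.append(f"n_mrcab_per_rg={self.n_mrcab_per_rg} (must be >= 1)")
        if self.channels < self.attention_channels:
            problems.append(
                f"channels={self.channels} < attention_channels={self.attention_channels}"
            )
        if self.upscale not in (1, 2):
            problems.append(f"upscale={self.upscale} (supported: 1 or 2)")
        if self.n_scales < 1:
            problems.append(f"n_scales={self.n_scales} (must be >= 1)")
        if self.kernel != 3:
            problems.append(f"kernel={self.kernel} (the architecture is defined for 3)")
        if problems:
            raise ValueError("invalid ModelConfig: " + "; ".join(problems))

    @property
    def divisibility(self) -> int:
        """Input dims must be divisible by this (stride-2 pyramid validity)."""
        return 2 ** (self.n_scales - 1)


class PFSRNet(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c, a, s = cfg.channels, cfg.attention_channels, cfg.lrelu_slope
        self.shallow = Conv3d(1, c, slope=s, rng=rng, dtype=dtype)
        self.multiscale = MultiscaleExtractor(c, a, cfg.n_scales, slope=s, rng=rng, dtype=dtype)
        self.spatial_attention = SpatialAttention(slope=s, rng=rng, dtype=dtype)
        self.groups = [
            ResidualGroup(c, a, cfg.n_mrcab_per_rg, slope=s, rng=rng, dtype=dtype)
            for _ in range(cfg.n_rg)
        ]
        r = cfg.upscale
        self.up_conv = Conv3d(c, c * r**3, slope=s, rng=rng, dtype=dtype)
        # zero-initialised: the untrained network is exactly trilinear interpolation
        self.final = Conv3d(c, 1, slope=s, rng=rng, zero_init=True, dtype=dtype)

    def _check_input(self, shape) -> None:
        div = self.cfg.divisibility
        bad = [n for n in shape[1:] if n % div != 0]
        if bad:
            raise ValueError(
                f"input spatial dims {tuple(shape[1:])} must be divisible by {div} "
                f"(stride-2 pyramid with {self.cfg.n_scales} scales)"
            )

    def __call__(self, x: Tensor) -> Tensor:
        """Forward pass; ``x`` has shape (1, D, H, W)."""
        cfg = self.cfg
        self._check_input(x.shape)
        f = ag.leaky_relu(self.shallow(x), cfg.lrelu_slope)
        f = self.multiscale(f)
        f = self.spatial_attention(f)
        y = f
        for rg in self.groups:
            y = rg(y)
        y = ag.leaky_relu(self.up_conv(y), cfg.lrelu_slope)
        if cfg.upscale > 1:
            y = ag.pixel_shuffle3d(y, cfg.upscale)
        residue = self.final(y)
        base = x
        for _ in range(cfg.upscale // 2):
            base = ag.upsample_trilinear2(base)
        return ag.add(residue, base)


def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> PFSRNet:
    """Build a (seeded, reproducible) PF-SR model from its configuration."""
    return PFSRNet(cfg, seed=seed, dtype=dtype)


def count_parameters(model: Module) -> int:
    """Exact number of independent learnable scalars (weights and biases)."""
    return int(sum(p.data.size for p in model.parameters()))


def subpixel_upsample(features: Tensor, r: int) -> Tensor:
    """3D pixel shuffle: r³ channel groups -> r-times finer spatial blocks."""
    return ag.pixel_shuffle3d(features, r)


def reconstruct(model: PFSRNet, vol: VolumeGrid) -> VolumeGrid:
    """Super-resolve a [0, 1] volume; output grid is ``upscale`` times finer."""
    model._check_input((1,) + tuple(vol.shape))
    x = Tensor(np.asarray(vol.values, dtype=model.final.weight.dtype)[None])
    with no_grad():
        y = model(x)
    out = y.data[0]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("reconstruction produced non-finite values")
    return vol.with_values(out, voxel_mm=vol.voxel_mm / model.cfg.upscale)


def save_checkpoint(model: PFSRNet, path, *, seed: int | None = None, epoch: int | None = None,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: architecture config + weights + metadata."""
    meta = {"seed": seed, "epoch": epoch, **(extra or {})}
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    np.savez(
        path,
        config_json=np.bytes_(json.dumps(asdict(model.cfg)).encode()),
        meta_json=np.bytes_(json.dumps(meta).encode()),
        **arrays,
    )


def load_checkpoint(path, cfg: ModelConfig | None = None) -> tuple[PFSRNet, dict]:
    """Rebuild a model from a checkpoint; refuses a mismatching expected config."""
    with np.load(path) as z:
        stored = ModelConfig(**json.loads(bytes(z["config_json"]).decode()))
        if cfg is not None and cfg != stored:
            raise ValueError(f"checkpoint config {stored} does not match expected {cfg}")
        meta = json.loads(bytes(z["meta_json"]).decode())
        model = build_model(stored)
        for name, p in model.named_parameters():
            key = f"param/{name}"
            if key not in z:
                raise ValueError(f"checkpoint is missing parameter {name}")
            data = z[key]
            if data.shape != p.data.shape:
                raise ValueError(f"parameter {name} has shape {data.shape}, expected {p.data.shape}")
            p.data = data
    return model, meta
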