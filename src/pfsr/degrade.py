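"""Synthesis of paired (low-resolution undersampled noisy, high-resolution clean) volumes.

This module emulates how ultralow-field (~0.055 T) 3D brain acquisitions
degrade a high-field, high-resolution volume:

1. symmetric k-space truncation downsamples the clean target by an integer
   factor (1.5 mm -> 3 mm by default) while deliberately retaining the Gibbs
   ringing that truncated spectra produce,
2. retrospective 2D partial-Fourier (PF) sampling removes a band of high
   positive frequencies on each of the two phase-encoding axes (fraction 0.7
   of lines kept per axis by default), optionally intersected with an
   elliptical phase-encode pattern,
3. the zero-filled magnitude reconstruction of the masked spectrum is
   corrupted with Rician noise (the magnitude statistics of complex Gaussian
   receiver noise),
4. both input and target are min-max normalised to [0, 1].

All spectra use the centered orthonormal convention of :mod:`pfsr.grid`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid, fft_centered, ifft_centered


@dataclass
class SamplingMask:
    """Binary k-space sampling indicator over the two phase-encoding axes.

    ``values`` is the 2D PE-plane pattern (LR axis first, SI axis second); it
    is broadcast as constant along the readout axis when applied to 3D
    spectra.  The mask always contains the fully sampled symmetric central
    band of each PE axis.
    """

    values: np.ndarray
    pf_fraction_lr: float
    pf_fraction_si: float
    elliptical: bool = False

    @property
    def n_sampled(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the full degradation chain.

    ``rician_sigma`` is the noise scale on the [0, 1]-normalised intensity
    scale; the experimental noise level of real ultralow-field scans is not a
    single number, so it is exposed as a swept parameter (default 0.05).
    """

    truncation_factor: int = 2
    pf_fraction: float = 0.7
    elliptical: bool = False
    rician_sigma: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.truncation_factor < 1:
            raise ValueError("truncation_factor must be >= 1")
        if not (0.5 < self.pf_fraction <= 1.0):
            raise ValueError("pf_fraction must lie in (0.5, 1.0]")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be >= 0")


def _check_divisible(shape, block: int) -> None:
    for axis, n in enumerate(shape):
        if n % block != 0:
            raise ValueError(f"axis {axis} of length {n} is not divisible by {block}")


def local_mean_downsample(vol: VolumeGrid, block: int) -> VolumeGrid:
    """Block-average downsampling: each output voxel is the mean of ``block``³ inputs."""
    if block < 1:
        raise ValueError("block must be >= 1")
    _check_divisible(vol.shape, block)
    v = vol.values
    n0, n1, n2 = (s // block for s in v.shape)
    out = v.reshape(n0, block, n1, block, n2, block).mean(axis=(1, 3, 5))
    return vol.with_values(out.astype(v.dtype), voxel_mm=vol.voxel_mm * block)


def kspace_truncate(vol: VolumeGrid, factor: int) -> VolumeGrid:
    """Downsample by keeping only the central ``(N/factor)``³ block of the spectrum.

    Unlike local averaging this reproduces how MR acquisition at lower
    resolution actually band-limits the object, so Gibbs ringing from the
    sharp spectral cut-off is present in the output.  The output is rescaled
    so that a constant volume maps to the same constant, and real parts are
    taken (the imaginary residue of a real input is roundoff).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    _check_divisible(vol.shape, factor)
    if factor == 1:
        return vol.with_values(vol.values.copy())
    spec = fft_centered(vol.values)
    slices = []
    for n in vol.shape:
        m = n // factor
        c = n // 2
        # central m samples of a centered spectrum: DC (at n//2) maps to m//2
        slices.append(slice(c - m // 2, c - m // 2 + m))
    cropped = spec[tuple(slices)]
    out = ifft_centered(cropped).real * factor ** (-1.5)
    return vol.with_values(out.astype(vol.values.dtype), voxel_mm=vol.voxel_mm * factor)


def _pf_band(n: int, fraction: float) -> np.ndarray:
    """Boolean acquisition band for one PE axis of a centered spectrum.

    The retained set is the full negative-frequency half plus the symmetric
    central band: contiguous indices ``0 .. ceil(f*n)-1`` with DC at
    ``n//2``.  This keeps one complete half-spectrum plus a symmetric
    calibration band around DC, which is what makes low-frequency phase
    estimation (POCS) well-posed.
    """
    if not (0.5 < fraction <= 1.0):
        raise ValueError(f"PF fraction must lie in (0.5, 1.0], got {fraction}")
    keep = math.ceil(fraction * n)
    band = np.zeros(n, dtype=bool)
    band[:keep] = True
    return band


def symmetric_band(n: int, fraction: float) -> np.ndarray:
    """The symmetric, Hermitian-complete central band implied by a PF fraction.

    For a band ``0..ceil(f*n)-1`` with DC at ``c = n//2`` the symmetric part
    is ``c-m .. c+m`` with ``m = ceil(f*n) - 1 - c``.
    """
    keep = math.ceil(fraction * n)
    c = n // 2
    m = keep - 1 - c
    if m < 0:
        raise ValueError(f"PF fraction {fraction} leaves no symmetric central band for n={n}")
    band = np.zeros(n, dtype=bool)
    band[c - m : c + m + 1] = True
    return band


def make_pf_mask(
    pe_shape: tuple[int, int],
    pf_lr: float = 0.7,
    pf_si: float = 0.7,
    elliptical: bool = False,
) -> SamplingMask:
    """Build the 2D phase-encode sampling mask.

    The mask is the outer product of the two per-axis PF bands; when
    ``elliptical`` is set it is additionally intersected with the inscribed
    ellipse measured from DC, emulating elliptical phase-encode ordering.
    """
    n_lr, n_si = pe_shape
    mask = np.outer(_pf_band(n_lr, pf_lr), _pf_band(n_si, pf_si))
    if elliptical:
        c1, c2 = n_lr // 2, n_si // 2
        k1 = (np.arange(n_lr) - c1)[:, None] / max(c1, 1)
        k2 = (np.arange(n_si) - c2)[None, :] / max(c2, 1)
        mask &= (k1**2 + k2**2) <= 1.0
    return SamplingMask(mask, pf_fraction_lr=pf_lr, pf_fraction_si=pf_si, elliptical=elliptical)


def broadcast_mask(mask: SamplingMask, vol: VolumeGrid) -> np.ndarray:
    """Expand the 2D PE-plane mask to the full 3D grid (constant along readout)."""
    ax_lr, ax_si = vol.pe_axes
    expected = (vol.shape[ax_lr], vol.shape[ax_si])
    if mask.values.shape != expected:
        raise ValueError(f"mask shape {mask.values.shape} does not match PE-plane shape {expected}")
    m2 = mask.values if ax_lr < ax_si else mask.values.T
    shape3 = [1, 1, 1]
    shape3[ax_lr] = vol.shape[ax_lr]
    shape3[ax_si] = vol.shape[ax_si]
    return np.broadcast_to(m2.reshape(shape3), vol.shape)


def zero_fill_reconstruct(vol: VolumeGrid, mask: SamplingMask) -> VolumeGrid:
    """Magnitude of the inverse transform of the masked spectrum (ZF reconstruction)."""
    m3 = broadcast_mask(mask, vol)
    spec = fft_centered(vol.values) * m3
    out = np.abs(ifft_centered(spec))
    return vol.with_values(out.astype(vol.values.dtype))


def add_rician_noise(vol: VolumeGrid, sigma: float, seed: int) -> VolumeGrid:
    """Replace each voxel v by sqrt((v + a)² + b²), a, b ~ N(0, sigma²) i.i.d.

    This is the magnitude of a complex signal of amplitude v corrupted by
    circular Gaussian noise; at v = 0 it reduces to a Rayleigh variate.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if np.any(vol.values < 0):
        raise ValueError("Rician noise applies to non-negative magnitude images")
    if sigma == 0:
        return vol.with_values(vol.values.copy())
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sigma, size=vol.shape)
    b = rng.normal(0.0, sigma, size=vol.shape)
    out = np.sqrt((vol.values + a) ** 2 + b**2)
    return vol.with_values(out.astype(vol.values.dtype))


def normalize_unit(vol: VolumeGrid) -> VolumeGrid:
    """Affine min-max map onto [0, 1]; a constant volume maps to all zeros."""
    v = vol.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("normalize_unit: constant volume has no intensity range; returning zeros")
        return vol.with_values(np.zeros_like(v))
    return vol.with_values(((v - lo) / (hi - lo)).astype(v.dtype))


def simulate_ulf_pair(highres: VolumeGrid, cfg: DegradationConfig) -> tuple[VolumeGrid, VolumeGrid]:
    """Run the full degradation chain; returns ``(input, target)``.

    ``target`` is the [0, 1]-normalised high-resolution volume; ``input`` is
    its k-space-truncated, PF-sampled, Rician-noisy, re-normalised
    low-resolution counterpart on the ``factor``-times coarser grid.  The
    result is a pure function of ``(highres, cfg)``.
    """
    cfg.validate()
    _check_divisible(highres.shape, cfg.truncation_factor)
    target = normalize_unit(highres)
    low = kspace_truncate(target, cfg.truncation_factor)
    ax_lr, ax_si = low.pe_axes
    mask = make_pf_mask(
        (low.shape[ax_lr], low.shape[ax_si]),
        pf_lr=cfg.pf_fraction,
        pf_si=cfg.pf_fraction,
        elliptical=cfg.elliptical,
    )
    zf = zero_fill_reconstruct(low, mask)
    noisy = add_rician_noise(zf, cfg.rician_sigma, cfg.seed)
    return normalize_unit(noisy), target
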