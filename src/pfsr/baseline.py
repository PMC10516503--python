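"""Analytical comparison pipeline: POCS partial-Fourier reconstruction,
3D denoising and tricubic 2x interpolation.

This is the traditional, non-learned counterpart of the PF-SR network.  The
partial-Fourier step exploits approximate Hermitian symmetry of k-space: the
image phase is estimated from the fully sampled symmetric central band, and
projections alternate between (i) imposing that low-frequency phase on the
current magnitude estimate and (ii) restoring the acquired k-space samples
(data consistency).  Because the readout axis is fully sampled, the 2D
per-slice POCS iteration can be evaluated with volumetric FFTs restricted to
the two phase-encoding axes (the transforms are separable), which is what
the implementation does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_nl_means, estimate_sigma

from .degrade import SamplingMask, broadcast_mask, symmetric_band
from .grid import VolumeGrid, fft_centered, ifft_centered


@dataclass(frozen=True)
class PocsConfig:
    n_iter: int = 10
    tol: float = 1e-6
    #: half-width (in samples) of the central band used for phase estimation;
    #: None derives the band from the mask's PF fractions
    phase_band: int | None = None

    def validate(self) -> None:
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def _hann_band(n: int, band: np.ndarray) -> np.ndarray:
    """Hann apodisation over a contiguous boolean band (non-zero at the edges)."""
    idx = np.flatnonzero(band)
    if idx.size == 0:
        raise ValueError("empty central band: low-frequency phase is unestimable")
    w = np.zeros(n)
    w[idx] = np.hanning(idx.size + 2)[1:-1]
    return w


def _band_from_mask(n: int, fraction: float, phase_band: int | None) -> np.ndarray:
    if phase_band is None:
        return symmetric_band(n, fraction)
    c = n // 2
    band = np.zeros(n, dtype=bool)
    band[max(0, c - phase_band) : min(n, c + phase_band + 1)] = True
    return band


def _pocs_core(
    kspace: np.ndarray,
    mask2d: np.ndarray,
    pe_axes: tuple[int, int],
    fractions: tuple[float, float],
    cfg: PocsConfig,
    return_complex: bool = False,
) -> np.ndarray:
    """POCS on centered k-space; returns the magnitude image."""
    cfg.validate()
    ax_lr, ax_si = pe_axes
    n_lr, n_si = kspace.shape[ax_lr], kspace.shape[ax_si]

    shape_lr = [1] * kspace.ndim
    shape_lr[ax_lr] = n_lr
    shape_si = [1] * kspace.ndim
    shape_si[ax_si] = n_si
    m3 = (
        (mask2d if ax_lr < ax_si else mask2d.T)
        .reshape([n_lr if a == ax_lr else (n_si if a == ax_si else 1) for a in range(kspace.ndim)])
    )
    data = kspace * m3

    w_lr = _hann_band(n_lr, _band_from_mask(n_lr, fractions[0], cfg.phase_band))
    w_si = _hann_band(n_si, _band_from_mask(n_si, fractions[1], cfg.phase_band))
    apod = w_lr.reshape(shape_lr) * w_si.reshape(shape_si)

    axes = pe_axes
    low = ifft_centered(data * apod, axes=axes)
    mag_low = np.abs(low)
    phase = np.where(mag_low > 0, low / np.where(mag_low > 0, mag_low, 1.0), 1.0)

    img = ifft_centered(data, axes=axes)  # zero-fill start
    for _ in range(cfg.n_iter):
        proj = np.abs(img) * phase
        k_new = fft_centered(proj, axes=axes)
        k_new = np.where(m3, data, k_new)
        img_new = ifft_centered(k_new, axes=axes)
        delta = np.linalg.norm(img_new - img) / max(np.linalg.norm(img), 1e-30)
        img = img_new
        if delta < cfg.tol:
            break
    return img if return_complex else np.abs(img)


def pocs_pf_reconstruct(
    vol: VolumeGrid | np.ndarray,
    mask: SamplingMask,
    cfg: PocsConfig | None = None,
    *,
    kspace: np.ndarray | None = None,
) -> VolumeGrid | np.ndarray:
    """Partial-Fourier POCS reconstruction.

    Accepts either a :class:`VolumeGrid` (3D; PE axes taken from its axis
    labels), a plain 2D array (a single PE-plane slice, possibly complex),
    or a pre-computed ``kspace`` array via keyword (centered, transformed
    along the PE axes only — the readout axis stays in the image domain).
    With ``n_iter=0`` the result is exactly the zero-filled magnitude image.
    """
    cfg = cfg or PocsConfig()
    fractions = (mask.pf_fraction_lr, mask.pf_fraction_si)
    if isinstance(vol, VolumeGrid):
        pe_axes = vol.pe_axes
        k = fft_centered(vol.values, axes=pe_axes) if kspace is None else kspace
        if mask.values.shape != (vol.shape[pe_axes[0]], vol.shape[pe_axes[1]]):
            raise ValueError("mask shape does not match the volume's PE-plane shape")
        out = _pocs_core(k, mask.values, pe_axes, fractions, cfg)
        return vol.with_values(out.astype(vol.values.dtype))
    arr = np.asarray(vol) if kspace is None else None
    if kspace is None:
        if arr.ndim != 2:
            raise ValueError("plain-array input must be a 2D PE-plane slice")
        k = fft_centered(arr)
    else:
        k = kspace
    if mask.values.shape != k.shape[-2:]:
        raise ValueError("mask shape does not match the slice shape")
    return _pocs_core(k, mask.values, (k.ndim - 2, k.ndim - 1), fractions, cfg)


def denoise3d(vol: VolumeGrid, method: str = "fallback", *, sigma: float | None = None) -> VolumeGrid:
    """Volumetric denoising behind a pluggable backend interface.

    ``"fallback"`` is 3D non-local means (patch-based averaging in a search
    window), which is deterministic and dependency-free.  ``"bm4d-wrapped"``
    delegates to the optional ``bm4d`` package (collaborative 4D transform
    filtering) when it is installed.
    """
    if method == "bm4d-wrapped":
        try:
            import bm4d  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "the 'bm4d-wrapped' backend requires the optional bm4d package; "
                "use method='fallback' (3D non-local means) instead"
            ) from exc
        sig = sigma if sigma is not None else float(estimate_sigma(vol.values))
        out = bm4d.bm4d(vol.values.astype(np.float64), sig)
        return vol.with_values(out.astype(vol.values.dtype))
    if method != "fallback":
        raise ValueError(f"unknown denoising backend {method!r}; use 'fallback' or 'bm4d-wrapped'")
    v = vol.values.astype(np.float64)
    sig = sigma if sigma is not None else float(estimate_sigma(v))
    out = denoise_nl_means(
        v, patch_size=3, patch_distance=5, h=0.8 * sig, sigma=sig, fast_mode=True
    )
    return vol.with_values(out.astype(vol.values.dtype))


# -- cubic-convolution (Catmull-Rom) interpolation ------------------------

def _catmull_rom_weights(f: np.ndarray) -> np.ndarray:
    """Weights for samples (i0-1, i0, i0+1, i0+2) at fraction f in [0, 1)."""
    f2, f3 = f * f, f * f * f
    return np.stack(
        [
            0.5 * (-f + 2 * f2 - f3),
            0.5 * (2 - 5 * f2 + 3 * f3),
            0.5 * (f + 4 * f2 - 3 * f3),
            0.5 * (-f2 + f3),
        ]
    )


def _cubic_up_axis(a: np.ndarray, axis: int, r: int) -> np.ndarray:
    """Cubic-convolution r-times upsampling along one axis (aligned, edge-clamped).

    Output sample j sits at input coordinate j / r, so every r-th output
    reproduces an input sample exactly (the kernel is interpolating).
    """
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    j = np.arange(n * r)
    p = j / r
    i0 = np.floor(p).astype(int)
    w = _catmull_rom_weights(p - i0)  # (4, n*r)
    out = np.zeros(a.shape[:-1] + (n * r,), dtype=np.result_type(a.dtype, np.float64))
    for k in range(4):
        idx = np.clip(i0 + k - 1, 0, n - 1)
        out += w[k] * a[..., idx]
    return np.moveaxis(out, -1, axis)


def tricubic_upsample(vol: VolumeGrid, r: int = 2) -> VolumeGrid:
    """Separable Catmull-Rom cubic interpolation, r-times finer per axis."""
    if any(n < 4 for n in vol.shape):
        raise ValueError(f"tricubic interpolation needs dims >= 4, got {vol.shape}")
    out = vol.values
    for ax in range(3):
        out = _cubic_up_axis(out, ax, r)
    return vol.with_values(out.astype(vol.values.dtype), voxel_mm=vol.voxel_mm / r)


def trilinear_upsample(vol: VolumeGrid, r: int = 2) -> VolumeGrid:
    """Aligned trilinear upsampling (the zero-fill comparator and the
    network's global-residual base use this same operator)."""
    if r == 1:
        return vol.with_values(vol.values.copy())
    if r != 2:
        raise ValueError("only r=2 is supported")
    from .nn.autograd import _up2_axis

    out = vol.values
    for ax in range(3):
        out = _up2_axis(out, ax)
    return vol.with_values(out, voxel_mm=vol.voxel_mm / r)


def non_dl_pipeline(
    vol: VolumeGrid,
    mask: SamplingMask,
    pocs_cfg: PocsConfig | None = None,
    denoise_method: str = "fallback",
) -> VolumeGrid:
    """POCS -> denoise -> tricubic 2x: the standard comparator for PF-SR."""
    pocs = pocs_pf_reconstruct(vol, mask, pocs_cfg)
    den = denoise3d(pocs, method=denoise_method)
    return tricubic_upsample(den, 2)
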