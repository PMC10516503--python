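"""Volumetric containers and centered-Fourier helpers.

The package works on isotropic 3D scalar volumes.  Axis semantics follow the
acquisition geometry of 3D fast-spin-echo brain imaging: one frequency-encoded
readout axis and two phase-encoded axes (left-right and superior-inferior).
Undersampling patterns only ever act on the two phase-encoding axes; the
readout axis is always fully sampled.

All spectra use the *centered, orthonormal* discrete Fourier convention: the
DC component sits at index ``floor(N/2)`` on every axis and forward/inverse
transforms are unitary, so Parseval's identity holds without scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: canonical axis labels, in storage order
READOUT = "readout"
PE_LR = "pe_lr"
PE_SI = "pe_si"
DEFAULT_AXES = (READOUT, PE_LR, PE_SI)


@dataclass
class VolumeGrid:
    """A real-valued 3D scalar field with isotropic voxel spacing.

    Parameters
    ----------
    values
        3D array of voxel intensities.
    voxel_mm
        Isotropic voxel spacing in millimetres.
    axes
        Ordered anatomical labels, a permutation of
        ``("readout", "pe_lr", "pe_si")``.
    """

    values: np.ndarray
    voxel_mm: float = 1.5
    axes: tuple[str, str, str] = DEFAULT_AXES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeGrid requires a 3D array, got ndim={self.values.ndim}")
        if any(n < 8 for n in self.values.shape):
            raise ValueError(f"all dimensions must be >= 8, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if sorted(self.axes) != sorted(DEFAULT_AXES):
            raise ValueError(f"axes must be a permutation of {DEFAULT_AXES}, got {self.axes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_index(self, label: str) -> int:
        """Position of the named anatomical axis in the storage order."""
        return self.axes.index(label)

    @property
    def pe_axes(self) -> tuple[int, int]:
        """Indices of the two phase-encoding axes (LR first, then SI)."""
        return (self.axis_index(PE_LR), self.axis_index(PE_SI))

    def with_values(self, values: np.ndarray, *, voxel_mm: float | None = None) -> "VolumeGrid":
        return replace(self, values=values, voxel_mm=self.voxel_mm if voxel_mm is None else voxel_mm)


@dataclass
class ComplexSpectrum:
    """Centered orthonormal 3D spectrum of a :class:`VolumeGrid` (DC at ``N//2``)."""

    values: np.ndarray
    voxel_mm: float = 1.5
    axes: tuple[str, str, str] = DEFAULT_AXES


def fft_centered(values: np.ndarray, axes=None) -> np.ndarray:
    """Orthonormal FFT with the zero-frequency bin moved to the array center."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(values, axes=axes), axes=axes, norm="ortho"), axes=axes)


def ifft_centered(values: np.ndarray, axes=None) -> np.ndarray:
    """Inverse of :func:`fft_centered`."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(values, axes=axes), axes=axes, norm="ortho"), axes=axes)


def spectrum_of(vol: VolumeGrid) -> ComplexSpectrum:
    return ComplexSpectrum(fft_centered(vol.values), voxel_mm=vol.voxel_mm, axes=vol.axes)


def volume_of(spec: ComplexSpectrum) -> VolumeGrid:
    """Real part of the inverse transform (imaginary residue must be roundoff)."""
    img = ifft_centered(spec.values)
    return VolumeGrid(np.ascontiguousarray(img.real), voxel_mm=spec.voxel_mm, axes=spec.axes)
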