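"""Procedural brain-like 3D phantoms with controllable ground-truth labels.

The generator produces piecewise-smooth volumes with four tissue classes
(background, CSF, gray matter, white matter) arranged as procedurally
deformed nested ellipsoids: a brain-shaped outer surface, a peripheral CSF
rim, a cortical gray-matter shell and a white-matter core, optionally
decorated with interior sub-structures (ellipsoidal ventricle-like CSF
cavities, sinusoidally folded cortical bands, thin vascular-like tubes).

Intensities are assigned per tissue class directly on the [0, 1] scale with
the complementary contrast behaviour of T1- and T2-weighted brain imaging:
white matter is brightest and CSF darkest in T1W-like volumes, and the
ordering flips in T2W-like volumes.  Within-class texture is zero-mean
smoothed Gaussian noise, which makes the volumes piecewise-smooth rather
than piecewise-constant (super-resolution is trivial on the latter).

Everything is a pure function of the spec and its seed, so entire cohorts
can be regenerated bit-identically from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import DEFAULT_AXES, VolumeGrid

# integer labels of the tissue classes
BACKGROUND, CSF, GRAY, WHITE = 0, 1, 2, 3
CLASS_NAMES = ("background", "csf", "gray", "white")


class Contrast(str, Enum):
    T1W = "t1w"
    T2W = "t2w"


@dataclass(frozen=True)
class TissueModel:
    """Per-class mean intensity and texture standard deviation on [0, 1]."""

    means: tuple[float, float, float, float]  # background, CSF, gray, white
    texture_sd: tuple[float, float, float, float] = (0.005, 0.02, 0.03, 0.03)

    def __post_init__(self):
        bg, csf, gm, wm = self.means
        t1_like = wm > gm > csf > bg
        t2_like = csf > gm > wm > bg
        if not (t1_like or t2_like):
            raise ValueError(
                "tissue means must satisfy the T1W-like (white>gray>CSF>background) "
                f"or T2W-like (CSF>gray>white>background) ordering, got {self.means}"
            )


#: default intensity models for the two contrasts
TISSUE_MODELS = {
    Contrast.T1W: TissueModel(means=(0.02, 0.25, 0.55, 0.85)),
    Contrast.T2W: TissueModel(means=(0.02, 0.90, 0.45, 0.25)),
}

# nested-ellipsoid radii (fractions of the normalised head radius)
_RHO_CSF = 0.90   # outer surface of gray matter / inner surface of the CSF rim
_RHO_GW = 0.68    # gray/white interface


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one phantom; identical specs yield identical volumes."""

    grid_size: int = 64
    voxel_mm: float = 1.5
    contrast: Contrast = Contrast.T1W
    n_structures: int = 6
    deformation_strength: float = 0.12
    texture_sd: float | None = None  # None -> per-class defaults of the TissueModel
    seed: int = 0
    semi_axes: tuple[float, float, float] = (0.88, 0.95, 0.90)

    def validate(self) -> None:
        if self.grid_size < 32 or self.grid_size % 2 != 0:
            raise ValueError(f"grid_size must be even and >= 32, got {self.grid_size}")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")
        if self.deformation_strength < 0:
            raise ValueError("deformation_strength must be >= 0")


@dataclass
class LabeledPhantom:
    """A generated volume plus its ground-truth tissue labels (test oracles only)."""

    volume: VolumeGrid
    labels: np.ndarray
    spec: PhantomSpec


def _normalised_coords(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = (np.arange(n) - (n - 1) / 2) / (n / 2)
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _smooth_unit_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smoothed white noise rescaled to unit per-voxel variance.

    The rescaling uses the exact l2 norm of the truncated Gaussian kernel
    (obtained by filtering an impulse), so the variance normalisation is
    analytic rather than sample-based.
    """
    noise = gaussian_filter(rng.standard_normal(shape), sigma, mode="constant")
    m = int(np.ceil(4 * sigma)) * 2 + 1
    impulse = np.zeros((m, m, m))
    impulse[m // 2, m // 2, m // 2] = 1.0
    knorm = np.sqrt(np.sum(gaussian_filter(impulse, sigma, mode="constant") ** 2))
    return noise / knorm


def _label_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.grid_size
    x, y, z = _normalised_coords(n)

    if spec.deformation_strength > 0:
        # smooth random warp of the coordinate frame before evaluating the
        # analytic geometry; amplitude is in normalised-radius units
        sig = n / 10
        x = x + spec.deformation_strength * _smooth_unit_noise(rng, x.shape, sig) * 0.5
        y = y + spec.deformation_strength * _smooth_unit_noise(rng, x.shape, sig) * 0.5
        z = z + spec.deformation_strength * _smooth_unit_noise(rng, x.shape, sig) * 0.5

    a, b, c = spec.semi_axes
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)

    # sinusoidal folding of the gray/white interface, accumulated from the
    # "folded cortical band" sub-structures
    theta = np.arctan2(np.sqrt(x**2 + y**2), z)
    phi = np.arctan2(y, x)
    gw = np.full_like(rho, _RHO_GW)

    ventricles: list[tuple] = []
    tubes: list[tuple] = []
    for i in range(spec.n_structures):
        kind = i % 3
        if kind == 0:  # ventricle-like CSF cavity
            centre = rng.uniform(-0.25, 0.25, size=3)
            semi = rng.uniform(0.08, 0.18, size=3)
            ventricles.append((centre, semi))
        elif kind == 1:  # folded cortical band
            k1 = rng.integers(3, 7)
            k2 = rng.integers(3, 7)
            p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
            gw = gw + 0.05 * np.sin(k1 * theta + p1) * np.cos(k2 * phi + p2)
        else:  # vascular-like tube running along z
            base = rng.uniform(-0.4, 0.4, size=2)
            amp = rng.uniform(0.05, 0.15)
            freq = rng.uniform(1.0, 2.5)
            ph = rng.uniform(0, 2 * np.pi)
            tubes.append((base, amp, freq, ph))

    labels = np.full((n, n, n), BACKGROUND, dtype=np.uint8)
    labels[rho <= 1.0] = CSF
    labels[rho <= _RHO_CSF] = GRAY
    labels[(rho <= gw) & (rho <= _RHO_CSF)] = WHITE

    for centre, semi in ventricles:
        r2 = ((x - centre[0]) / semi[0]) ** 2 + ((y - centre[1]) / semi[1]) ** 2 + (
            (z - centre[2]) / semi[2]
        ) ** 2
        labels[(r2 <= 1.0) & (rho <= _RHO_CSF)] = CSF

    for (base, amp, freq, ph) in tubes:
        cx = base[0] + amp * np.sin(freq * np.pi * z + ph)
        cy = base[1] + amp * np.cos(freq * np.pi * z + ph)
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        labels[(d2 <= 0.03**2) & (rho <= _RHO_CSF)] = CSF

    # hard background margin: the head never touches the volume edge, so the
    # boundary shell stays near zero even under strong deformation
    margin = 2
    edge = np.ones_like(labels, dtype=bool)
    edge[margin:-margin, margin:-margin, margin:-margin] = False
    labels[edge] = BACKGROUND
    return labels


def generate_labeled_phantom(spec: PhantomSpec) -> LabeledPhantom:
    """Generate one phantom together with its ground-truth label field."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _label_field(spec, rng)

    tissue = TISSUE_MODELS[Contrast(spec.contrast)]
    means = np.asarray(tissue.means)
    if spec.texture_sd is None:
        sds = np.asarray(tissue.texture_sd)
    else:
        sds = np.full(4, float(spec.texture_sd))

    texture = _smooth_unit_noise(rng, labels.shape, 0.8)
    values = means[labels] + sds[labels] * texture
    np.clip(values, 0.0, 1.0, out=values)

    vol = VolumeGrid(values.astype(np.float32), voxel_mm=spec.voxel_mm, axes=DEFAULT_AXES)
    return LabeledPhantom(volume=vol, labels=labels, spec=spec)


def generate_phantom(spec: PhantomSpec) -> VolumeGrid:
    """Generate one brain-like volume (see :func:`generate_labeled_phantom`)."""
    return generate_labeled_phantom(spec).volume


def generate_cohort(n: int, base_spec: PhantomSpec, seed: int) -> list[LabeledPhantom]:
    """Generate ``n`` phantoms with per-subject randomised geometry.

    Per-item seeds and geometric jitter are derived deterministically from the
    cohort seed, so the full cohort is a pure function of ``(base_spec, seed)``.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    children = np.random.SeedSequence(seed).spawn(n)
    cohort = []
    for child in children:
        rng = np.random.default_rng(child)
        item_seed = int(rng.integers(0, 2**31 - 1))
        jitter = rng.uniform(0.93, 1.07, size=3)
        axes = tuple(np.asarray(base_spec.semi_axes) * jitter)
        spec = replace(base_spec, seed=item_seed, semi_axes=axes)
        cohort.append(generate_labeled_phantom(spec))
    return cohort
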