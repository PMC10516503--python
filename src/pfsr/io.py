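"""Standard-format I/O: NIfTI volumes, HDF5 paired datasets, YAML run configs.

Volumes are stored as float32 NIfTI with the isotropic voxel spacing in the
header and the anatomical axis labels recorded in the header description.
The method assumes isotropic grids, so anisotropic inputs are rejected
rather than silently resampled.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .baseline import PocsConfig
from .degrade import DegradationConfig
from .grid import DEFAULT_AXES, VolumeGrid
from .nn.model import ModelConfig
from .phantom import Contrast, LabeledPhantom, PhantomSpec
from .training import TrainConfig

_AXES_TAG = "axes="


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write as NIfTI (.nii or .nii.gz); spacing and axis labels go in the header."""
    affine = np.diag([vol.voxel_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header["descrip"] = (_AXES_TAG + ",".join(vol.axes)).encode()
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp" + "".join(path.suffixes))
    nib.save(img, tmp)
    os.replace(tmp, path)


def read_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI volume; refuses anisotropic spacing (>1% deviation)."""
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if zooms.max() > 1.01 * zooms.min():
        raise ValueError(
            f"anisotropic voxel spacing {tuple(zooms)} mm: this pipeline assumes "
            "isotropic volumes; resample the input first"
        )
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
    axes = DEFAULT_AXES
    if descrip.startswith(_AXES_TAG):
        parsed = tuple(descrip[len(_AXES_TAG):].split(","))
        if sorted(parsed) == sorted(DEFAULT_AXES):
            axes = parsed  # type: ignore[assignment]
    values = np.asarray(img.get_fdata(dtype=np.float32))
    return VolumeGrid(values, voxel_mm=float(zooms.mean()), axes=axes)


def write_pairs(path: str | Path, pairs: list[tuple[VolumeGrid, VolumeGrid]],
                config: DegradationConfig | None = None) -> None:
    """Paired-dataset container: /inputs, /targets (+ /config as JSON attr)."""
    with h5py.File(path, "w") as fh:
        gin = fh.create_group("inputs")
        gtg = fh.create_group("targets")
        for i, (inp, tgt) in enumerate(pairs):
            din = gin.create_dataset(f"{i:05d}", data=inp.values.astype(np.float32))
            din.attrs["voxel_mm"] = inp.voxel_mm
            dtg = gtg.create_dataset(f"{i:05d}", data=tgt.values.astype(np.float32))
            dtg.attrs["voxel_mm"] = tgt.voxel_mm
        if config is not None:
            fh.attrs["config_json"] = json.dumps(asdict(config))


def read_pairs(path: str | Path) -> tuple[list[tuple[VolumeGrid, VolumeGrid]], DegradationConfig | None]:
    with h5py.File(path, "r") as fh:
        keys = sorted(fh["inputs"].keys())
        pairs = []
        for k in keys:
            din, dtg = fh["inputs"][k], fh["targets"][k]
            pairs.append(
                (
                    VolumeGrid(din[()], voxel_mm=float(din.attrs["voxel_mm"])),
                    VolumeGrid(dtg[()], voxel_mm=float(dtg.attrs["voxel_mm"])),
                )
            )
        cfg = None
        if "config_json" in fh.attrs:
            cfg = DegradationConfig(**json.loads(fh.attrs["config_json"]))
    return pairs, cfg


def write_cohort(path: str | Path, cohort: list[LabeledPhantom]) -> None:
    """Cohort container with /volumes, /labels, /specs groups."""
    with h5py.File(path, "w") as fh:
        gv = fh.create_group("volumes")
        gl = fh.create_group("labels")
        gs = fh.create_group("specs")
        for i, item in enumerate(cohort):
            key = f"{i:05d}"
            dv = gv.create_dataset(key, data=item.volume.values.astype(np.float32))
            dv.attrs["voxel_mm"] = item.volume.voxel_mm
            gl.create_dataset(key, data=item.labels)
            spec = asdict(item.spec)
            spec["contrast"] = Contrast(spec["contrast"]).value
            gs.create_dataset(key, data=json.dumps(spec))


# -- run configuration ----------------------------------------------------

_STAGE_ORDER = ("phantom", "degradation", "model", "train", "pocs")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the global seed."""
    idx = _STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """All stage configurations plus the global seed; serialises losslessly to YAML."""

    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationConfig = field(default_factory=DegradationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    pocs: PocsConfig = field(default_factory=PocsConfig)

    def __post_init__(self):
        # stage seeds derive from the global seed unless explicitly overridden
        if self.phantom.seed == 0:
            object.__setattr__(self.phantom, "seed", derive_seed(self.seed, "phantom"))
        if self.degradation.seed == 0:
            object.__setattr__(self.degradation, "seed", derive_seed(self.seed, "degradation"))
        if self.train.seed == 0:
            object.__setattr__(self.train, "seed", derive_seed(self.seed, "train"))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "phantom": asdict(self.phantom),
            "degradation": asdict(self.degradation),
            "model": asdict(self.model),
            "train": asdict(self.train),
            "pocs": asdict(self.pocs),
        }
        payload["phantom"]["contrast"] = Contrast(payload["phantom"]["contrast"]).value
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        phantom = dict(payload.get("phantom", {}))
        if "contrast" in phantom:
            phantom["contrast"] = Contrast(phantom["contrast"])
        if "semi_axes" in phantom:
            phantom["semi_axes"] = tuple(phantom["semi_axes"])
        train = dict(payload.get("train", {}))
        if "betas" in train:
            train["betas"] = tuple(train["betas"])
        return cls(
            seed=payload.get("seed", 0),
            phantom=PhantomSpec(**phantom),
            degradation=DegradationConfig(**payload.get("degradation", {})),
            model=ModelConfig(**payload.get("model", {})),
            train=TrainConfig(**train),
            pocs=PocsConfig(**payload.get("pocs", {})),
        )
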