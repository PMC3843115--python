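"""Voxel containers shared across the pipeline.

Everything downstream of image generation operates on a regular voxel grid:
a greyscale :class:`VoxelImage` and a categorical :class:`LabelMap` with one
tissue label per voxel.  Conventions, fixed package-wide:

* array axes are (lateral, anterior-posterior, axial); the third axis points
  cranially (axial compression is applied along it),
* voxel indices are 0-based and world coordinates use the voxel-centre rule
  ``world = origin + (index + 0.5) * voxel_size``,
* lengths are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelImage",
    "LabelMap",
    "BACKGROUND",
    "LABEL_NAMES",
    "LABEL_IDS",
    "LEVELS",
    "trabecular_label",
    "cortical_label",
    "cement_label",
    "bone_labels",
    "vertebra_labels",
]

#: anatomical levels of the segment, cranial to caudal
LEVELS = ("T12", "L1", "L2")

BACKGROUND = 0

#: fixed integer coding of every tissue the phantom can contain
LABEL_NAMES: dict[int, str] = {
    0: "background",
    1: "trabecular_T12",
    2: "cortical_T12",
    3: "trabecular_L1",
    4: "cortical_L1",
    5: "trabecular_L2",
    6: "cortical_L2",
    7: "annulus_upper",
    8: "nucleus_upper",
    9: "annulus_lower",
    10: "nucleus_lower",
    11: "housing_top",
    12: "housing_bottom",
    13: "cement_T12",
    14: "cement_L1",
    15: "cement_L2",
}

LABEL_IDS: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}


def trabecular_label(level: str) -> int:
    return LABEL_IDS[f"trabecular_{level}"]


def cortical_label(level: str) -> int:
    return LABEL_IDS[f"cortical_{level}"]


def cement_label(level: str) -> int:
    return LABEL_IDS[f"cement_{level}"]


def bone_labels() -> tuple[int, ...]:
    """Labels whose modulus is element-specific (mapped from greyscale)."""
    out = []
    for lv in LEVELS:
        out += [trabecular_label(lv), cortical_label(lv)]
    return tuple(out)


def vertebra_labels(level: str, include_cement: bool = True) -> tuple[int, ...]:
    """Labels making up one vertebral body (its cement region included by
    default, since augmented voxels are still part of the body volume)."""
    out = [trabecular_label(level), cortical_label(level)]
    if include_cement:
        out.append(cement_label(level))
    return tuple(out)


def _affine(voxel_size: float, origin: np.ndarray) -> np.ndarray:
    aff = np.diag([voxel_size] * 3 + [1.0])
    aff[:3, 3] = origin
    return aff


@dataclass
class VoxelImage:
    """A 3-D greyscale field on a regular grid."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("image data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite greyscale values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres, one 1-D array per axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size
            for a in range(3)
        )

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), _affine(self.voxel_size, self.origin))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelImage":
        img = nib.load(str(path))
        aff = img.affine
        vs = float(aff[0, 0])
        return cls(np.asarray(img.dataobj, dtype=float), vs, aff[:3, 3].copy())


@dataclass
class LabelMap:
    """Categorical tissue labels on the same grid as a :class:`VoxelImage`.

    ``names`` maps label integers to tissue names; it defaults to the fixed
    package-wide scheme and is written alongside NIfTI output as a JSON
    sidecar so label files are self-describing.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.data, labels)

    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.data, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def copy(self) -> "LabelMap":
        return replace(self, data=self.data.copy(), names=dict(self.names))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.uint16), _affine(self.voxel_size, self.origin))
        nib.save(img, str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        sidecar = Path(str(sidecar) + "_labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in self.names.items()}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabelMap":
        path = Path(path)
        img = nib.load(str(path))
        aff = img.affine
        names = dict(LABEL_NAMES)
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + "_labels.json")
        if sidecar.exists():
            names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return cls(
            np.asarray(img.dataobj).astype(np.int64),
            float(aff[0, 0]),
            aff[:3, 3].copy(),
            names,
        )
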