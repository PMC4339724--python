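"""Shared voxel-grid containers and tissue label codes.

Conventions used throughout the package:

* voxel indices are 0-based;
* an *axial slice* is an index along the **third** array axis, so a slice
  is the 2-D plane spanned by axes (0, 1) = (row, col);
* tissue label codes are fixed everywhere as ``BG=0, CSF=1, GM=2, WM=3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np

BG, CSF, GM, WM = 0, 1, 2, 3
LABEL_CODES: Tuple[int, ...] = (BG, CSF, GM, WM)
CLASS_NAMES: Mapping[int, str] = {BG: "BG", CSF: "CSF", GM: "GM", WM: "WM"}
#: the three tissue classes quantified in volumetry (background excluded)
TISSUE_CODES: Tuple[int, ...] = (CSF, GM, WM)


def _as_voxel_size(voxel_size_mm) -> Tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size_mm)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size_mm must be 3 positive floats, got {voxel_size_mm!r}")
    return vs


@dataclass
class MultispectralVolume:
    """C co-registered intensity channels on one 3-D voxel grid.

    ``data`` has shape ``(nx, ny, nz, C)`` with C >= 2 (multispectral by
    definition); ``channel_names`` orders the channels.
    """

    data: np.ndarray
    channel_names: Sequence[str]
    voxel_size_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D (nx, ny, nz, C) array, got shape {self.data.shape}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[3]} channels"
            )
        if self.n_channels < 2:
            raise ValueError("a multispectral volume needs at least 2 channels")
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channel_names.index(name)]


@dataclass
class LabelVolume:
    """Integer tissue map (BG/CSF/GM/WM) on a 3-D voxel grid."""

    labels: np.ndarray
    voxel_size_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D label grid, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        bad = np.setdiff1d(np.unique(self.labels), LABEL_CODES)
        if bad.size:
            raise ValueError(f"undeclared label codes present: {bad.tolist()}")
        self.labels = self.labels.astype(np.int16)
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def class_counts(self) -> Mapping[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(LABEL_CODES))
        return {code: int(counts[code]) for code in LABEL_CODES}


@dataclass
class BrainMask:
    """Boolean voxel mask congruent with the image grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected 3-D mask, got shape {self.mask.shape}")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TrainingSeeds:
    """Operator input: one axial slice plus a small square patch per class.

    ``patch_centers`` maps a label code to the (row, col) center of its
    patch within the seed slice.  The default 3x3 patch yields 9 voxels
    per class, 36 training samples for four classes.
    """

    slice_index: int
    patch_centers: Mapping[int, Tuple[int, int]]
    patch_size: int = 3

    def __post_init__(self) -> None:
        self.slice_index = int(self.slice_index)
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be a positive odd integer")
        centers = {}
        for code, rc in dict(self.patch_centers).items():
            code = int(code)
            if code not in LABEL_CODES:
                raise ValueError(f"unknown class code {code} in seeds")
            centers[code] = (int(rc[0]), int(rc[1]))
        if not centers:
            raise ValueError("seeds must declare at least one class patch")
        self.patch_centers = centers

    @property
    def classes(self) -> Tuple[int, ...]:
        return tuple(sorted(self.patch_centers))
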