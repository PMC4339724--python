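"""Reading/writing volumes and assembling the voxel-by-channel feature matrix.

Images, label maps and masks travel as NIfTI-1 (.nii / .nii.gz) through
nibabel; raw unsigned-byte or 16-bit volumes (the simulated-brain database's
native download format) are decoded with an explicitly declared shape and
dtype.  Seed coordinates round-trip through a small JSON schema.
"""

from __future__ import annotations

import json
import os
from typing import Sequence, Tuple

import nibabel as nib
import numpy as np

from .types import BrainMask, LabelVolume, MultispectralVolume, TrainingSeeds

_RAW_DTYPES = {"uint8": np.uint8, "int16": np.int16, "uint16": np.uint16}


def _load_nifti(path):
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine, img.header.get_zooms()[:3]


def read_multispectral(paths: Sequence, channel_names: Sequence[str] | None = None
                       ) -> MultispectralVolume:
    """Stack co-registered single-channel NIfTI volumes into one feature cube.

    All files must share grid shape and affine; voxel size is taken from the
    first header.  At least two channels are required.
    """
    paths = list(paths)
    if len(paths) < 2:
        raise ValueError("multispectral input needs at least 2 channel files")
    if channel_names is None:
        channel_names = [os.path.basename(str(p)).split(".")[0] for p in paths]
    if len(channel_names) != len(paths):
        raise ValueError("channel_names must match the number of files")
    arrays, ref_affine, ref_zooms = [], None, None
    for name, path in zip(channel_names, paths):
        data, affine, zooms = _load_nifti(path)
        if data.ndim != 3:
            raise ValueError(f"channel {name!r}: expected a 3-D volume, got shape {data.shape}")
        if ref_affine is None:
            ref_affine, ref_zooms, ref_shape = affine, zooms, data.shape
        else:
            if data.shape != ref_shape:
                raise ValueError(
                    f"channel {name!r} grid {data.shape} mismatches first channel {ref_shape}"
                )
            if not np.allclose(affine, ref_affine, atol=1e-4):
                raise ValueError(f"channel {name!r} affine mismatches first channel")
        arrays.append(np.asarray(data, dtype=np.float64))
    return MultispectralVolume(
        np.stack(arrays, axis=-1), channel_names=channel_names,
        voxel_size_mm=ref_zooms, affine=ref_affine,
    )


def write_multispectral(vol: MultispectralVolume, paths: Sequence) -> None:
    """One NIfTI file per channel, in channel order."""
    if len(paths) != vol.n_channels:
        raise ValueError(f"need {vol.n_channels} output paths, got {len(paths)}")
    for c, path in enumerate(paths):
        nib.save(nib.Nifti1Image(vol.data[..., c], vol.affine), str(path))


def read_brainweb_raw(path, shape: Tuple[int, int, int], dtype_code: str = "uint8"
                      ) -> np.ndarray:
    """Decode a raw binary volume (e.g. a .rawb download) of declared shape.

    The file is interpreted with the first axis varying fastest (Fortran
    order), the download convention of the simulated-brain database, giving an
    (x, y, z) array with z the axial axis.
    """
    if dtype_code not in _RAW_DTYPES:
        raise ValueError(f"dtype_code must be one of {sorted(_RAW_DTYPES)}")
    dtype = np.dtype(_RAW_DTYPES[dtype_code])
    shape = tuple(int(n) for n in shape)
    expected = int(np.prod(shape)) * dtype.itemsize
    actual = os.path.getsize(path)
    if actual != expected:
        raise ValueError(
            f"{path}: expected {expected} bytes for shape {shape} {dtype_code}, found {actual}"
        )
    flat = np.fromfile(path, dtype=dtype)
    return flat.reshape(shape, order="F")


def write_brainweb_raw(array: np.ndarray, path, dtype_code: str = "uint8") -> None:
    if dtype_code not in _RAW_DTYPES:
        raise ValueError(f"dtype_code must be one of {sorted(_RAW_DTYPES)}")
    np.asarray(array, dtype=_RAW_DTYPES[dtype_code]).ravel(order="F").tofile(path)


def write_labels(labels: LabelVolume, path) -> None:
    """Integer NIfTI label map; read_labels(write_labels(x)) == x."""
    if not str(path):
        raise ValueError("empty output path")
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine), str(path))


def read_labels(path) -> LabelVolume:
    data, affine, zooms = _load_nifti(path)
    return LabelVolume(np.asarray(data).astype(np.int16), voxel_size_mm=zooms, affine=affine)


def write_mask(mask: BrainMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4)), str(path))


def read_mask(path) -> BrainMask:
    data, _, _ = _load_nifti(path)
    return BrainMask(np.asarray(data) > 0)


def fallback_mask(vol: MultispectralVolume) -> BrainMask:
    """All voxels with nonzero intensity in every channel.

    A stand-in when no externally produced (skull-stripped) mask exists,
    e.g. for phantoms whose background is exactly zero.
    """
    return BrainMask(np.all(vol.data != 0, axis=-1))


def flatten_to_features(vol: MultispectralVolume, mask: BrainMask
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """One row per in-mask voxel, one column per channel.

    Returns ``(features, index)`` where ``index`` is the (N, 3) array of voxel
    coordinates in C order; ``unflatten_labels`` inverts the mapping exactly.
    """
    if mask.grid_shape != vol.grid_shape:
        raise ValueError(f"mask grid {mask.grid_shape} mismatches volume {vol.grid_shape}")
    if mask.n_voxels == 0:
        raise ValueError("empty mask: nothing to classify")
    index = np.argwhere(mask.mask)
    features = vol.data[mask.mask]
    return features, index


def unflatten_labels(values: np.ndarray, index: np.ndarray,
                     grid_shape: Tuple[int, int, int], fill: int = 0) -> np.ndarray:
    out = np.full(grid_shape, fill, dtype=np.int16)
    out[index[:, 0], index[:, 1], index[:, 2]] = values
    return out


# -- seeds file (JSON) ----------------------------------------------------

def write_seeds(seeds: TrainingSeeds, path) -> None:
    payload = {
        "slice_index": seeds.slice_index,
        "patch_size": seeds.patch_size,
        "patch_centers": {str(code): list(rc) for code, rc in seeds.patch_centers.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_seeds(path) -> TrainingSeeds:
    with open(path) as fh:
        payload = json.load(fh)
    return TrainingSeeds(
        slice_index=payload["slice_index"],
        patch_centers={int(k): tuple(v) for k, v in payload["patch_centers"].items()},
        patch_size=payload.get("patch_size", 3),
    )
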