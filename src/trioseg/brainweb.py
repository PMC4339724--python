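"""Loading the public simulated-brain (BrainWeb) database for benchmarking.

The database ships 181 x 217 x 181 voxel, 1 mm isotropic volumes as raw
unsigned-byte downloads: simulated T1/T2/PD acquisitions on a noise x
intensity-non-uniformity grid (file stems like ``t1_icbm_normal_1mm_pn3_rf0``)
plus a crisp anatomical model giving each voxel's dominant tissue.  This
module decodes those files, remaps the crisp model onto the package's four
classes, restricts to an axial slice band (default: the central 90 of 181
slices), and fixes documented seed-patch coordinates so a benchmark run is
fully reproducible.

The data are freely downloadable but not redistributable, so nothing here is
bundled; point ``load_dataset`` at a directory of downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from . import io
from .types import BG, CSF, GM, WM, BrainMask, LabelVolume, MultispectralVolume, TrainingSeeds

SHAPE: Tuple[int, int, int] = (181, 217, 181)
CHANNELS = ("T1", "T2", "PD")

#: crisp anatomical-model codes of the database
CRISP_BG, CRISP_CSF, CRISP_GM, CRISP_WM, CRISP_GLIAL = 0, 1, 2, 3, 8

#: fixed operator seed placement: mid-slice of the full volume (axial z=90),
#: (row=x, col=y) patch centers chosen on the atlas anatomy — ventricular CSF
#: near the volume center, deep frontal WM, posterior cortical GM, air BG.
DEFAULT_SEEDS = TrainingSeeds(
    slice_index=90,
    patch_centers={CSF: (90, 110), WM: (64, 100), GM: (90, 180), BG: (10, 10)},
    patch_size=3,
)


def _stem(channel: str, noise: int, rf: int) -> str:
    return f"{channel.lower()}_icbm_normal_1mm_pn{int(noise)}_rf{int(rf)}.rawb"


def remap_crisp(crisp: np.ndarray, glial_as_gm: bool = True) -> np.ndarray:
    """Crisp anatomical codes -> {BG, CSF, GM, WM}; non-brain classes -> BG."""
    out = np.full(crisp.shape, BG, dtype=np.int16)
    out[crisp == CRISP_CSF] = CSF
    out[crisp == CRISP_GM] = GM
    out[crisp == CRISP_WM] = WM
    if glial_as_gm:
        out[crisp == CRISP_GLIAL] = GM
    return out


def central_slices(n_slices: int = 90, total: int = SHAPE[2]) -> slice:
    start = (total - n_slices) // 2
    return slice(start, start + n_slices)


@dataclass
class BrainWebCase:
    image: MultispectralVolume
    truth: LabelVolume
    mask: BrainMask
    seeds: TrainingSeeds
    noise: int
    rf: int


def load_dataset(data_dir, noise: int, rf: int,
                 slice_range: slice | None = None,
                 channels: Sequence[str] = CHANNELS,
                 seeds: TrainingSeeds = DEFAULT_SEEDS,
                 glial_as_gm: bool = True) -> BrainWebCase:
    """Assemble one noise/rf configuration from downloaded raw volumes.

    The evaluation mask keeps air and the three tissues and drops skull,
    scalp, fat etc. — emulating an exact skull strip from the anatomical
    model while retaining background as a classifiable class.
    """
    sl = central_slices() if slice_range is None else slice_range
    stacks = []
    for ch in channels:
        path = os.path.join(data_dir, _stem(ch, noise, rf))
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"missing {path}; download the simulated volume for channel {ch}, "
                f"{noise}% noise, {rf}% non-uniformity into {data_dir}"
            )
        stacks.append(io.read_brainweb_raw(path, SHAPE, "uint8").astype(np.float64))
    crisp_path = os.path.join(data_dir, "phantom_1.0mm_normal_crisp.rawb")
    if not os.path.exists(crisp_path):
        raise FileNotFoundError(f"missing crisp anatomical model {crisp_path}")
    crisp = io.read_brainweb_raw(crisp_path, SHAPE, "uint8")

    image = np.stack(stacks, axis=-1)[:, :, sl, :]
    crisp = crisp[:, :, sl]
    truth = remap_crisp(crisp, glial_as_gm=glial_as_gm)
    keep = (CRISP_BG, CRISP_CSF, CRISP_GM, CRISP_WM) + ((CRISP_GLIAL,) if glial_as_gm else ())
    mask = np.isin(crisp, keep)

    seed_slice = seeds.slice_index - sl.start
    if not 0 <= seed_slice < image.shape[2]:
        raise ValueError(
            f"seed slice {seeds.slice_index} falls outside the selected slice band"
        )
    local_seeds = TrainingSeeds(
        slice_index=seed_slice, patch_centers=dict(seeds.patch_centers),
        patch_size=seeds.patch_size,
    )
    return BrainWebCase(
        image=MultispectralVolume(image, channel_names=list(channels)),
        truth=LabelVolume(truth),
        mask=BrainMask(mask),
        seeds=local_seeds, noise=int(noise), rf=int(rf),
    )
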