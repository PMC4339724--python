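"""Synthetic multispectral brain-like phantoms with controlled noise and bias.

The generator emulates the public simulated-brain (BrainWeb-style) test
conditions: 1 mm isotropic multispectral volumes with four classes
(background, CSF, gray matter, white matter), Gaussian noise whose standard
deviation is a percentage of the brightest tissue mean, and a smooth
multiplicative intensity non-uniformity ("RF") field with a stated
peak-to-peak amplitude (20% -> multiplicative range [0.90, 1.10]).

Geometry is a set of nested ellipsoidal shells (BG outside, CSF rim, GM
shell, WM core, plus a central ellipsoidal ventricle relabeled CSF).  It is
deliberately not anatomically realistic: the classifier under test is purely
voxel-intensity based, with no spatial prior, so shell topology is enough to
exercise every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import yaml

from .types import BG, CSF, GM, WM, LABEL_CODES, BrainMask, LabelVolume, MultispectralVolume, TrainingSeeds

#: default per-class, per-channel mean intensities (rows BG, CSF, GM, WM).
#: Implementation constants chosen to give the canonical tissue contrast:
#: T1: WM > GM > CSF;  T2: CSF > GM > WM;  FLAIR: GM > WM >> CSF.
DEFAULT_CLASS_MEANS: Tuple[Tuple[float, ...], ...] = (
    (5.0, 5.0, 5.0),        # BG
    (50.0, 180.0, 30.0),    # CSF
    (120.0, 100.0, 140.0),  # GM
    (160.0, 70.0, 110.0),   # WM
)
DEFAULT_CHANNELS = ("T1", "T2", "FLAIR")

# normalized ellipsoid radii of the shell boundaries (fractions of the
# outer brain semi-axes) and of the central ventricle
_BRAIN_SEMIAXIS_FRACTION = 0.46
_CSF_INNER, _GM_INNER, _VENTRICLE = 0.92, 0.62, 0.25


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom realization."""

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    class_means: Sequence[Sequence[float]] = DEFAULT_CLASS_MEANS
    noise_percent: float = 0.0
    nonuniformity_percent: float = 0.0
    rng_seed: int = 0
    rician_noise: bool = False

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must have 3 axes")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.channel_names = list(self.channel_names)
        means = np.asarray(self.class_means, dtype=np.float64)
        if means.shape != (4, len(self.channel_names)):
            raise ValueError(
                f"class_means must be 4 x {len(self.channel_names)} "
                f"(BG, CSF, GM, WM rows), got shape {means.shape}"
            )
        if (means < 0).any():
            raise ValueError("class_means must be non-negative")
        self.class_means = means
        for name, value in (("noise_percent", self.noise_percent),
                            ("nonuniformity_percent", self.nonuniformity_percent)):
            if not 0.0 <= float(value) <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {value}")
        self.noise_percent = float(self.noise_percent)
        self.nonuniformity_percent = float(self.nonuniformity_percent)
        self.rng_seed = int(self.rng_seed)

    @property
    def brightest_mean(self) -> float:
        """Largest class-channel mean — the 'brightest tissue' the noise % refers to."""
        return float(self.class_means.max())

    @property
    def noise_sigma(self) -> float:
        return self.noise_percent / 100.0 * self.brightest_mean

    # -- plain-text (YAML) round-trip -------------------------------------
    def to_dict(self) -> Dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": list(self.voxel_size_mm),
            "channel_names": list(self.channel_names),
            "class_means": np.asarray(self.class_means).tolist(),
            "noise_percent": self.noise_percent,
            "nonuniformity_percent": self.nonuniformity_percent,
            "rng_seed": self.rng_seed,
            "rician_noise": self.rician_noise,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Phantom:
    """A rendered phantom: intensities, ground-truth labels and bias fields."""

    image: MultispectralVolume
    truth: LabelVolume
    bias_field: np.ndarray  # (nx, ny, nz, C), multiplicative, == 1 where disabled
    spec: PhantomSpec

    def brain_mask(self) -> BrainMask:
        """Ground-truth brain mask: all non-background voxels."""
        return BrainMask(self.truth.labels != BG)


def _normalized_radius(grid_shape: Tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal radius normalized so the outer brain surface is at 1."""
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in grid_shape]
    semi = [_BRAIN_SEMIAXIS_FRACTION * n for n in grid_shape]
    xs = [ax / s for ax, s in zip(axes, semi)]
    return np.sqrt(
        xs[0][:, None, None] ** 2 + xs[1][None, :, None] ** 2 + xs[2][None, None, :] ** 2
    )


def generate_geometry(spec: PhantomSpec) -> LabelVolume:
    """Nested-ellipsoid label map: BG, CSF rim, GM shell, WM core, CSF ventricle.

    Raises ``ValueError`` if the grid is too small to hold all shells (each of
    the four labels must occupy at least 1% of the grid).
    """
    if min(spec.grid_shape) < 16:
        raise ValueError(
            f"grid {spec.grid_shape} too small: each axis must be >= 16 voxels "
            "so that the four nested tissue shells all fit"
        )
    rho = _normalized_radius(spec.grid_shape)
    labels = np.full(spec.grid_shape, BG, dtype=np.int16)
    labels[rho <= 1.0] = CSF
    labels[rho <= _CSF_INNER] = GM
    labels[rho <= _GM_INNER] = WM
    labels[rho <= _VENTRICLE] = CSF  # central "ventricle"
    counts = np.bincount(labels.ravel(), minlength=4)
    n = labels.size
    deficient = [code for code in LABEL_CODES if counts[code] < 0.01 * n]
    if deficient:
        raise ValueError(
            f"grid {spec.grid_shape} too small: labels {deficient} occupy < 1% of voxels"
        )
    return LabelVolume(labels, voxel_size_mm=spec.voxel_size_mm)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth separable per-axis quadratic multiplicative field, one per channel.

    The raw field (a product of per-axis quadratics with random coefficients)
    is affinely rescaled so its grid min/max equal 1 -/+ a/2 exactly, with
    a = nonuniformity_percent/100; a == 0 yields an exact all-ones field.
    """
    shape = spec.grid_shape
    C = len(spec.channel_names)
    out = np.ones(shape + (C,), dtype=np.float64)
    a = spec.nonuniformity_percent / 100.0
    if a == 0.0:
        return out
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    for c in range(C):
        field = np.ones(shape)
        for axis, u in enumerate(coords):
            b1, b2 = rng.uniform(-0.5, 0.5, size=2)
            q = 1.0 + b1 * u + b2 * u**2
            shape_ax = [1, 1, 1]
            shape_ax[axis] = len(u)
            field = field * q.reshape(shape_ax)
        lo, hi = field.min(), field.max()
        if hi - lo < 1e-12:  # degenerate draw: fall back to a pure x-gradient
            u = coords[0].reshape(-1, 1, 1)
            field = np.broadcast_to(1.0 + 0.5 * u, shape).copy()
            lo, hi = field.min(), field.max()
        out[..., c] = (1.0 - a / 2.0) + (field - lo) * (a / (hi - lo))
    return out


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Render intensities from geometry: means x bias + noise.

    Voxel v, channel c gets ``class_means[truth(v), c] * bias(v, c) + eps``
    with eps Gaussian of sigma = noise_percent/100 x brightest class-channel
    mean.  With ``rician_noise=True`` the magnitude-image Rician model is used
    instead (two independent Gaussian quadrature components).
    """
    truth = generate_geometry(spec)
    rng = np.random.default_rng(spec.rng_seed)
    bias = _bias_field(spec, rng)
    clean = spec.class_means[truth.labels] * bias  # (nx, ny, nz, C)
    sigma = spec.noise_sigma
    if sigma == 0.0:
        data = clean
    elif spec.rician_noise:
        n1 = rng.normal(0.0, sigma, size=clean.shape)
        n2 = rng.normal(0.0, sigma, size=clean.shape)
        data = np.sqrt((clean + n1) ** 2 + n2**2)
    else:
        data = clean + rng.normal(0.0, sigma, size=clean.shape)
    image = MultispectralVolume(
        data, channel_names=spec.channel_names, voxel_size_mm=spec.voxel_size_mm
    )
    return Phantom(image=image, truth=truth, bias_field=bias, spec=spec)


def default_brainweb_like_spec(noise_percent: float, nonuniformity_percent: float,
                               rng_seed: int = 0,
                               grid_shape: Tuple[int, int, int] = (64, 64, 64)) -> PhantomSpec:
    """Spec with 1 mm voxels and the canonical multispectral contrast table."""
    return PhantomSpec(
        grid_shape=grid_shape,
        noise_percent=noise_percent,
        nonuniformity_percent=nonuniformity_percent,
        rng_seed=rng_seed,
    )


def default_seeds(spec: PhantomSpec, side: str = "east",
                  patch_size: int = 3) -> TrainingSeeds:
    """Deterministic valid seed placement on the phantom's central axial slice.

    Scans the central row of the central slice away from the grid center
    (``side='east'`` toward increasing columns, ``'west'`` decreasing) and, for
    each class, takes the median column whose whole patch lies in that class.
    The CSF patch lands in the central ventricle, offset off-center so that
    'east' and 'west' placements are disjoint (used to probe operator
    robustness).
    """
    if side not in ("east", "west"):
        raise ValueError("side must be 'east' or 'west'")
    truth = generate_geometry(spec).labels
    nz = spec.grid_shape[2]
    k = nz // 2
    plane = truth[:, :, k]
    row = spec.grid_shape[0] // 2
    c0 = spec.grid_shape[1] // 2
    half = patch_size // 2
    if side == "east":
        cols = range(c0 + 1, spec.grid_shape[1] - half)
    else:
        cols = range(c0 - 1, half - 1, -1)
    candidates: Dict[int, list] = {code: [] for code in LABEL_CODES}
    for col in cols:
        patch = plane[row - half: row + half + 1, col - half: col + half + 1]
        vals = np.unique(patch)
        if vals.size == 1:
            candidates[int(vals[0])].append(col)
    centers = {}
    for code in LABEL_CODES:
        cand = candidates[code]
        if not cand and code == BG:
            # the brain rim can reach the last columns of the central row;
            # background is always available in the slice corner of this side
            corner = (half, spec.grid_shape[1] - 1 - half) if side == "east" else (half, half)
            patch = plane[corner[0] - half: corner[0] + half + 1,
                          corner[1] - half: corner[1] + half + 1]
            if np.all(patch == BG):
                centers[BG] = corner
                continue
        if not cand:
            raise ValueError(
                f"no uniform {patch_size}x{patch_size} patch of class {code} found "
                f"on the {side} half of slice {k}; grid too small for seeding"
            )
        centers[code] = (row, cand[len(cand) // 2])
    return TrainingSeeds(slice_index=k, patch_centers=centers, patch_size=patch_size)
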