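"""The hybrid multispectral tissue classifier.

The pipeline couples three classical pattern-recognition stages, applied to
the voxel-by-channel feature matrix of a co-registered multispectral volume:

1. **Sphering (whitening)** — remove the first two statistical moments so
   features have zero mean and identity covariance; optionally rotate the
   sphered features into statistically independent components (ICA), which
   enhances tissue contrast and makes the downstream kernel classifier
   insensitive to its hyperparameters.
2. **Seed SVM** — an operator marks one small square patch (default 3x3, 9
   voxels) per class on a single axial slice; an RBF-kernel max-margin
   classifier trained on those 36 samples labels every in-mask voxel of that
   slice, turning a tiny manual input into a large training pool.
3. **Iterative Fisher linear discriminant analysis (IFLDA)** — Fisher's
   discriminant fitted on the current training pool classifies the whole
   volume; the resulting whole-volume labeling becomes the next training set,
   iterated until the labeling stabilizes.

Fisher's criterion maximizes the ratio x' S_B x / x' S_W x of between-class
to within-class scatter; for p classes it yields p-1 discriminant directions
(the rank of S_B).  Voxels are assigned to the nearest class centroid in
that discriminant space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.linalg
import yaml
from scipy.stats import kurtosis, skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from . import io
from .types import BG, LABEL_CODES, BrainMask, LabelVolume, MultispectralVolume, TrainingSeeds


# ---------------------------------------------------------------------------
# sphering
# ---------------------------------------------------------------------------

@dataclass
class SpheringModel:
    """Zero-mean, identity-covariance linear transform and its inverse."""

    channel_mean: np.ndarray
    whitening: np.ndarray      # C x C
    dewhitening: np.ndarray    # C x C inverse

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=np.float64) - self.channel_mean) @ self.whitening.T

    def inverse_transform(self, sphered: np.ndarray) -> np.ndarray:
        return np.asarray(sphered) @ self.dewhitening.T + self.channel_mean


def fit_sphering(features: np.ndarray, ridge: float = 0.0) -> SpheringModel:
    """Fit the whitening transform (ZCA square root of the sample covariance).

    ``ridge`` is an absolute diagonal loading added to the covariance before
    inversion; with ``ridge=0`` a rank-deficient covariance is rejected.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (voxels x channels)")
    n, c = X.shape
    if n < c + 1:
        raise ValueError(f"need at least C+1 = {c + 1} samples to sphere, got {n}")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(c, c)
    vals, vecs = np.linalg.eigh(cov + ridge * np.eye(c))
    if vals.min() <= 1e-12 * max(vals.max(), 1.0):
        raise np.linalg.LinAlgError(
            "channel covariance is rank-deficient (a constant or collinear channel); "
            "pass a small ridge > 0 to regularize"
        )
    W = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    Winv = vecs @ np.diag(np.sqrt(vals)) @ vecs.T
    return SpheringModel(channel_mean=mean, whitening=W, dewhitening=Winv)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class IcaModel:
    """Unmixing rotation on sphered data: s = W x, x = A s, W A = I."""

    unmixing: np.ndarray        # p x C
    mixing: np.ndarray          # C x p
    component_kurtosis: np.ndarray
    rng_seed: int

    def transform(self, sphered: np.ndarray) -> np.ndarray:
        return np.asarray(sphered) @ self.unmixing.T


def ica_unmix(sphered: np.ndarray, n_components: int | None = None, seed: int = 0,
              max_iter: int = 500, tol: float = 1e-5) -> Tuple[IcaModel, np.ndarray]:
    """Unmix sphered features into statistically independent components.

    Components are normalized by a fixed rule so the decomposition is
    reproducible: sorted by descending excess kurtosis, signed so each score
    distribution has non-negative skewness (falling back to a positive
    leading unmixing coefficient for symmetric scores).

    Raises ``RuntimeError`` if the fixed-point iteration does not converge.
    """
    X = np.asarray(sphered, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("sphered features must be 2-D")
    c = X.shape[1]
    p = c if n_components is None else int(n_components)
    if not 1 <= p <= c:
        raise ValueError(f"n_components must lie in [1, {c}]")
    cov = np.cov(X, rowvar=False, ddof=1).reshape(c, c)
    if not np.allclose(cov, np.eye(c), atol=1e-3):
        raise ValueError("input is not sphered: covariance deviates from identity")
    ica = FastICA(
        n_components=p,
        whiten=False if p == c else "unit-variance",
        max_iter=max_iter, tol=tol, random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise RuntimeError(
                f"ICA did not converge within {max_iter} sweeps (n_iter={ica.n_iter_}, "
                f"tol={tol}); increase max_iter or relax tol"
            )
    W = np.asarray(ica.components_, dtype=np.float64)
    mean = getattr(ica, "mean_", None)
    X0 = X - mean if mean is not None else X
    scores = X0 @ W.T
    kurt = kurtosis(scores, axis=0, fisher=True, bias=True)
    order = np.argsort(-kurt, kind="stable")
    W = W[order]
    kurt = kurt[order]
    scores = scores[:, order]
    sk = skew(scores, axis=0, bias=True)
    for j in range(p):
        if abs(sk[j]) > 1e-8:
            flip = sk[j] < 0
        else:
            lead = W[j, np.argmax(np.abs(W[j]) > 1e-12 * np.abs(W[j]).max())]
            flip = lead < 0
        if flip:
            W[j] = -W[j]
            scores[:, j] = -scores[:, j]
    A = np.linalg.pinv(W)
    model = IcaModel(unmixing=W, mixing=A, component_kurtosis=kurt, rng_seed=seed)
    return model, scores


# ---------------------------------------------------------------------------
# training samples
# ---------------------------------------------------------------------------

@dataclass
class LabeledSampleSet:
    """Feature rows with class labels and a provenance tag."""

    features: np.ndarray
    labels: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def extract_seed_samples(feature_volume: np.ndarray, seeds: TrainingSeeds,
                         mask: BrainMask | None = None) -> LabeledSampleSet:
    """Pull the operator's per-class patches out of a (nx, ny, nz, F) feature grid.

    Exactly ``patch_size**2`` samples per declared class; patches must lie
    fully inside the slice (and mask, if given) and must not overlap.
    """
    fvol = np.asarray(feature_volume)
    if fvol.ndim != 4:
        raise ValueError("feature_volume must be 4-D (nx, ny, nz, F)")
    nx, ny, nz, _ = fvol.shape
    k = seeds.slice_index
    if not 0 <= k < nz:
        raise ValueError(f"seed slice {k} outside volume ({nz} axial slices)")
    half = seeds.patch_size // 2
    taken: Dict[Tuple[int, int], int] = {}
    rows, labels = [], []
    for code in sorted(seeds.patch_centers):
        r, c = seeds.patch_centers[code]
        if not (half <= r < nx - half and half <= c < ny - half):
            raise ValueError(
                f"class {code} patch centered at ({r}, {c}) runs outside slice {k}"
            )
        for dr in range(-half, half + 1):
            for dc in range(-half, half + 1):
                rc = (r + dr, c + dc)
                if rc in taken:
                    raise ValueError(
                        f"class {code} patch overlaps class {taken[rc]} patch at {rc}"
                    )
                if mask is not None and not mask.mask[rc[0], rc[1], k]:
                    raise ValueError(
                        f"class {code} patch voxel {rc} on slice {k} is outside the mask"
                    )
                taken[rc] = code
                rows.append(fvol[rc[0], rc[1], k])
                labels.append(code)
    return LabeledSampleSet(np.array(rows), np.array(labels), provenance="seed")


# ---------------------------------------------------------------------------
# seed-slice SVM
# ---------------------------------------------------------------------------

def svm_classify_slice(seed_samples: LabeledSampleSet, slice_features: np.ndarray,
                       cost: float = 1.0, gamma: str | float = "scale",
                       required_classes: Sequence[int] = LABEL_CODES) -> LabeledSampleSet:
    """Label every in-mask voxel of the seed slice with an RBF-kernel SVM.

    Hyperparameters are deliberately plain (cost 1, kernel width 1/(C * Var),
    one-vs-one multi-class): after sphering/ICA the classes are well spread,
    so tuned kernels buy nothing.  The output is the "large pool" of training
    samples that initiates the iterative discriminant stage.
    """
    missing = sorted(set(int(c) for c in required_classes) - set(seed_samples.classes.tolist()))
    if missing:
        raise ValueError(f"seed samples lack required classes {missing}")
    X = np.asarray(slice_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("seed slice has no in-mask voxels to classify")
    if X.shape[1] != seed_samples.features.shape[1]:
        raise ValueError("slice feature dimension mismatches seed samples")
    svm = SVC(C=cost, kernel="rbf", gamma=gamma, decision_function_shape="ovo")
    svm.fit(seed_samples.features, seed_samples.labels)
    pred = svm.predict(X).astype(np.int16)
    return LabeledSampleSet(X, pred, provenance="svm_slice")


# ---------------------------------------------------------------------------
# Fisher's linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class FldaModel:
    """Fisher discriminant projection plus class centroids in discriminant space.

    ``projection`` holds the p-1 discriminant directions as columns (unit
    Euclidean norm, leading nonzero component positive, descending
    generalized eigenvalue); scatter matrices are retained for diagnostics.
    """

    projection: np.ndarray          # F x (p-1)
    class_codes: Tuple[int, ...]
    centroids: np.ndarray           # p x (p-1)
    S_W: np.ndarray
    S_B: np.ndarray
    S_T: np.ndarray
    eigenvalues: np.ndarray
    ridge_used: float

    def project(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=np.float64) @ self.projection

    def fisher_ratio(self, direction: np.ndarray) -> float:
        """x' S_B x / x' S_W x for an arbitrary direction x (diagnostic)."""
        x = np.asarray(direction, dtype=np.float64)
        return float(x @ self.S_B @ x) / float(x @ self.S_W @ x)


def scatter_matrices(features: np.ndarray, labels: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Dict[int, np.ndarray]]:
    """Within-class, between-class and total scatter (unnormalized sums).

    S_W = sum_j sum_{r in C_j} (r - mu_j)(r - mu_j)',
    S_B = sum_j n_j (mu_j - mu)(mu_j - mu)',
    S_T = sum_i (r_i - mu)(r_i - mu)'  ( = S_W + S_B ).
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[0] == np.asarray(labels).shape[0]:
        pass
    else:
        raise ValueError("features/labels length mismatch")
    y = np.asarray(labels)
    mu = X.mean(axis=0)
    F = X.shape[1]
    S_W = np.zeros((F, F))
    S_B = np.zeros((F, F))
    class_means: Dict[int, np.ndarray] = {}
    for code in np.unique(y):
        Xj = X[y == code]
        mu_j = Xj.mean(axis=0)
        class_means[int(code)] = mu_j
        D = Xj - mu_j
        S_W += D.T @ D
        d = (mu_j - mu)[:, None]
        S_B += Xj.shape[0] * (d @ d.T)
    D = X - mu
    S_T = D.T @ D
    return S_W, S_B, S_T, class_means


def _sign_fix(vecs: np.ndarray) -> np.ndarray:
    """Unit-norm columns with the first significantly nonzero entry positive."""
    out = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def fit_flda(samples: LabeledSampleSet, ridge: float = 1e-6) -> FldaModel:
    """Fit Fisher's discriminant: top p-1 eigenvectors of (S_W + eps I)^-1 S_B.

    ``ridge`` scales the diagonal loading eps = ridge * trace(S_W)/F applied
    to S_W before solving the generalized eigenproblem; when the within-class
    scatter is exactly zero (perfectly separable degenerate data) the loading
    falls back to ridge * trace(S_T)/F so the problem stays well posed.
    With ``ridge=0`` a singular S_W is rejected.
    """
    X, y = samples.features, samples.labels
    codes = np.unique(y)
    if codes.size < 2:
        raise ValueError("FLDA needs at least 2 classes in the training set")
    for code in codes:
        if (y == code).sum() < 2:
            raise ValueError(f"class {int(code)} has fewer than 2 samples")
    S_W, S_B, S_T, class_means = scatter_matrices(X, y)
    F = X.shape[1]
    p = codes.size
    trace_w = np.trace(S_W)
    eps = ridge * (trace_w if trace_w > 0 else np.trace(S_T)) / F
    if eps == 0.0:
        # exact solve: reject singular within-class scatter
        if np.linalg.matrix_rank(S_W) < F:
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; refit with a small ridge > 0"
            )
    vals, vecs = scipy.linalg.eigh(S_B, S_W + eps * np.eye(F))
    n_dirs = min(p - 1, F)
    top = np.argsort(vals)[::-1][:n_dirs]
    projection = _sign_fix(vecs[:, top])
    eigenvalues = vals[top]
    centroids = np.stack([class_means[int(c)] @ projection for c in codes])
    return FldaModel(
        projection=projection, class_codes=tuple(int(c) for c in codes),
        centroids=centroids, S_W=S_W, S_B=S_B, S_T=S_T,
        eigenvalues=eigenvalues, ridge_used=float(eps),
    )


def flda_classify(model: FldaModel, features: np.ndarray) -> np.ndarray:
    """Nearest class centroid (Euclidean) in discriminant space; ties go to
    the lowest class code (centroids are stored in ascending code order and
    argmin returns the first minimum)."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} mismatches model ({model.projection.shape[0]})"
        )
    Z = model.project(X)
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray(model.class_codes, dtype=np.int16)[idx]


@dataclass
class IterationTrace:
    """Per-iteration fraction of in-mask voxels whose label changed."""

    changed_fractions: List[float]
    converged: bool
    tolerance: float
    max_iterations: int

    @property
    def n_iterations(self) -> int:
        return len(self.changed_fractions)


def iterate_flda(initial: LabeledSampleSet, all_features: np.ndarray,
                 tolerance: float = 1e-3, max_iterations: int = 20,
                 ridge: float = 1e-6) -> Tuple[np.ndarray, IterationTrace, FldaModel]:
    """Self-training discriminant loop over the whole in-mask feature set.

    Each round fits FLDA on the current training pool, classifies every
    in-mask voxel, and uses the freshly labeled volume as the next pool;
    stops when the fraction of changed labels drops to ``tolerance`` or at
    ``max_iterations``.  If a class shrinks below 2 samples mid-iteration the
    loop terminates flagged non-convergent, returning the last labeling.
    """
    X = np.asarray(all_features, dtype=np.float64)
    samples = initial
    prev: np.ndarray | None = None
    fractions: List[float] = []
    converged = False
    model = None
    for _ in range(max_iterations):
        model = fit_flda(samples, ridge=ridge)
        labels = flda_classify(model, X)
        frac = 1.0 if prev is None else float(np.mean(labels != prev))
        fractions.append(frac)
        prev = labels
        if frac <= tolerance:
            converged = True
            break
        counts = np.bincount(labels, minlength=max(model.class_codes) + 1)
        if any(counts[c] < 2 for c in model.class_codes):
            converged = False
            break
        samples = LabeledSampleSet(X, labels, provenance=f"flda_iter_{len(fractions)}")
    trace = IterationTrace(
        changed_fractions=fractions, converged=converged,
        tolerance=tolerance, max_iterations=max_iterations,
    )
    return prev, trace, model


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SegmentConfig:
    """Tunable knobs of the pipeline, all with documented defaults."""

    use_ica: bool = True
    n_components: int | None = None   # None -> number of channels
    ica_seed: int = 0
    ica_max_iter: int = 500
    svm_cost: float = 1.0
    svm_gamma: str | float = "scale"  # 1 / (C * feature variance)
    tolerance: float = 1e-3           # stop when < 0.1% of labels change
    max_iterations: int = 20
    ridge: float = 1e-6
    sphering_ridge: float = 0.0

    def to_dict(self) -> Dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SegmentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and hasattr(exc, "add_note"):
                exc.add_note(f"pipeline stage: {name}")
            return False
    return _Ctx()


def segment(volume: MultispectralVolume, mask: BrainMask, seeds: TrainingSeeds,
            config: SegmentConfig | None = None
            ) -> Tuple[LabelVolume, IterationTrace, Dict[str, object]]:
    """Run the full pipeline on a co-registered, masked multispectral volume.

    flatten -> sphere -> (ICA) -> seed patches -> seed-slice SVM -> iterative
    FLDA over every in-mask voxel -> labels written back to the 3-D grid
    (out-of-mask voxels get BG).  Deterministic for fixed inputs and config.
    """
    config = config or SegmentConfig()
    models: Dict[str, object] = {}
    with _stage("flatten"):
        features, index = io.flatten_to_features(volume, mask)
    with _stage("sphering"):
        sph = fit_sphering(features, ridge=config.sphering_ridge)
        Z = sph.transform(features)
        models["sphering"] = sph
    if config.use_ica:
        with _stage("ica"):
            ica, Z = ica_unmix(
                Z, n_components=config.n_components,
                seed=config.ica_seed, max_iter=config.ica_max_iter,
            )
            models["ica"] = ica
    with _stage("seed_extraction"):
        fvol = np.zeros(volume.grid_shape + (Z.shape[1],))
        fvol[mask.mask] = Z
        seed_set = extract_seed_samples(fvol, seeds, mask=mask)
        models["seed_samples"] = seed_set
    with _stage("svm"):
        on_slice = index[:, 2] == seeds.slice_index
        svm_set = svm_classify_slice(
            seed_set, Z[on_slice], cost=config.svm_cost, gamma=config.svm_gamma,
            required_classes=seeds.classes,
        )
        models["svm_slice"] = svm_set
    with _stage("iflda"):
        flat_labels, trace, flda = iterate_flda(
            svm_set, Z, tolerance=config.tolerance,
            max_iterations=config.max_iterations, ridge=config.ridge,
        )
        models["flda"] = flda
    grid = io.unflatten_labels(flat_labels, index, volume.grid_shape, fill=BG)
    labels = LabelVolume(grid, voxel_size_mm=volume.voxel_size_mm, affine=volume.affine)
    return labels, trace, models


def export_models(models: Dict[str, object], path) -> None:
    """Audit dump of the fitted pipeline models as JSON."""
    def encode(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: encode(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        return obj
    with open(path, "w") as fh:
        json.dump({k: encode(v) for k, v in models.items()}, fh, indent=2)
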