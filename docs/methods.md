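# Methods

## Model and assumptions

The classifier is purely voxel-intensity based.  Each in-mask voxel of a
co-registered multispectral volume contributes a feature vector of its C
channel intensities (C ≥ 2; typically T1/T2/FLAIR or T1/T2/PD); no spatial
neighborhood, atlas prior or probability map enters the decision.  The method
therefore assumes the inputs are already rigidly co-registered, bias-corrected
and skull-stripped — those preprocessing steps are an external contract (they
are routinely done with standard tools: rigid registration of T2/FLAIR to T1,
N3 non-uniformity correction, BET skull stripping with fractional intensity
threshold 0.5 and threshold gradient 0.0), and the package consumes their
output.  A fallback mask (voxels nonzero in every channel) is provided for
phantoms.  Class codes are fixed as BG=0, CSF=1, GM=2, WM=3; voxel indices are
0-based and an axial slice is an index along the third array axis.

### Sphering and ICA

Whitening uses the ZCA (symmetric) inverse square root of the sample
covariance (ddof = 1), computed by eigendecomposition: deterministic,
invertible, and exactly satisfying the contract that the transformed training
data have zero mean and identity covariance.  An optional ridge (absolute
diagonal loading, default 0) guards collinear channels; a rank-deficient
covariance without ridge is rejected rather than silently pseudo-inverted.

Full ICA is an optional rotation applied after whitening (default **on**).
The literature on this hybrid design is ambiguous about whether the kernel
stage consumes sphered channels or independent components; since ICA of
pre-whitened data is an orthogonal rotation, it cannot reduce separability,
and it demonstrably relieves the SVM of kernel tuning, so it is on by default
and exposed as a config flag.  The FastICA fixed-point algorithm
(scikit-learn) does the estimation; components are then normalized by a fixed
convention — sorted by descending excess kurtosis, signed so each score
distribution has non-negative skewness (symmetric scores fall back to a
positive leading unmixing coefficient) — making the decomposition reproducible
across runs and platforms.  Non-convergence raises with iteration diagnostics
instead of returning a half-converged rotation.

### Seed patches and the slice SVM

The operator marks one square patch per class (default 3×3 = 9 voxels; 36
samples for four classes) on a single axial slice.  Patches must lie fully
inside the slice and the mask and must not overlap.  An RBF-kernel SVM with
cost C = 1, kernel width γ = 1/(C·Var(features)) and one-vs-one multi-class
voting, trained on the 36 seed samples, labels every in-mask voxel of the seed
slice.  The hyperparameters are deliberately plain and fixed: after
sphering/ICA the class clusters are compact and well spread, so tuned kernels
buy nothing — which is precisely why this stage can run without operator
expertise.

### Iterative Fisher LDA

Scatter matrices are the unnormalized sums
S_W = Σ_j Σ_{r∈C_j}(r−μ_j)(r−μ_j)ᵀ, S_B = Σ_j n_j(μ_j−μ)(μ_j−μ)ᵀ,
S_T = Σ_i(r_i−μ)(r_i−μ)ᵀ = S_W + S_B (the identity is verified on every fit to
1e-8 relative).  The projection takes the top p−1 eigenvectors of
(S_W + εI)⁻¹S_B via the symmetric-definite generalized eigensolver, for p
classes present in the training pool.  Eigenvectors are unit-norm with the
first significantly nonzero component positive, sorted by descending
eigenvalue — a pure convention that pins the model bit-for-bit across runs.

**Ridge.**  ε = 1e-6 · trace(S_W)/C by default.  On perfectly separable
degenerate data (e.g. a zero-noise phantom) S_W is exactly zero and that rule
degenerates to ε = 0; the implementation then falls back to
ε = 1e-6 · trace(S_T)/C so the eigenproblem stays well posed and the
separable case remains solvable.  With ridge = 0 a singular S_W is an error
recommending regularization.

**Decision rule.**  Nearest class centroid (Euclidean) in the (p−1)-dim
discriminant space; exact ties go to the lowest class code.  This is the
simplest rule consistent with the Fisher projection; it needs no density
model.

**Iteration.**  fit → classify all in-mask voxels → refit on the whole freshly
labeled volume, until the fraction of changed labels ≤ 0.1% (configurable) or
20 iterations.  The first iteration's changed fraction is defined as 1.0
(there is no previous whole-volume labeling).  If a class shrinks below two
samples mid-iteration the loop stops, flags non-convergence, and returns the
last labeling rather than crashing or silently dropping the class.  On
separable data the loop provably reaches its fixed point at iteration 2 with
zero changes — exercised as a test.

The SVM stage classifies a single slice (the seed slice); whole-volume
information enters through the iterated discriminant.  This matches the
observation that the kernel stage performs well one slice at a time, and keeps
its cost negligible.

## The phantom generator

The generator emulates the public simulated-brain database's test grid, not
its anatomy: nested ellipsoidal shells (BG outside, a CSF rim, a GM shell, a
WM core, and a central ellipsoidal "ventricle" relabeled CSF) on a 1 mm
isotropic grid, with each class guaranteed ≥ 1% of the voxels.  Intensities
are class means × a multiplicative bias field + Gaussian noise:

* **Class-mean table** (implementation constants): BG (5,5,5),
  CSF (50,180,30), GM (120,100,140), WM (160,70,110) for (T1, T2, FLAIR) —
  the canonical contrast ordering (T1: WM>GM>CSF; T2: CSF>GM>WM;
  FLAIR: GM>WM≫CSF) with the brightest class-channel mean 180 (CSF on T2).
* **Noise**: σ = noise%/100 × the brightest class-channel mean ("relative to
  the brightest tissue").  Additive Gaussian by default; a Rician
  (magnitude-image) option exists but is off — at the 0–5% levels tested the
  difference on bright tissue is negligible.
* **Bias field**: per channel, a product of per-axis quadratics with
  seeded random coefficients, affinely rescaled so its grid min/max equal
  1∓a/2 exactly, a = nonuniformity%/100; "20% non-uniformity" therefore means
  the multiplicative range [0.90, 1.10], the database's documented convention.
  a = 0 yields an exactly-one field.

Geometry is independent of the intensity settings, so class frequencies are
invariant across the noise/bias grid, and identical (spec, seed) pairs render
bit-identical phantoms.

**What passing phantom tests does and does not show.**  The phantom has no
partial-volume voxels, no anatomical shape complexity, no MR sequence physics,
and its classes are far apart relative to the tested noise (at 3% noise the
pipeline recovers the truth essentially exactly, where the real database—with
partial volume and anatomy—yields similarity indexes near 0.95).  Phantom
results therefore validate the algorithmic contracts (separable-case exact
recovery, monotone degradation with noise, operator robustness, determinism),
not clinical accuracy.

## Benchmark against the real simulated-brain database

`trioseg.brainweb` decodes the 181×217×181 raw unsigned-byte downloads
(Fortran voxel order), remaps the crisp anatomical model to the four classes
(glial matter counted as GM; non-brain classes masked out, emulating an exact
skull strip while keeping air as classifiable background), restricts to the
central 90 of 181 axial slices (the published experiments used 90 slices; the
exact selection is not stated, so the centered band is the default and a flag
overrides it), and fixes documented seed coordinates on axial slice 90
(ventricular CSF (90,110), deep WM (64,100), posterior cortical GM (90,180),
air BG (10,10)).  The data are freely downloadable but not redistributable,
so nothing is bundled; the seed loci were chosen from atlas anatomy and the
corresponding benchmark test reports a clear error until the download is
present.

## Evaluation conventions

* Similarity index implemented as 2|X∩Y|/(|X|+|Y|) — the Dice coefficient.
  (One published description of this formula calls the ∩ operation a union;
  the symbol, the metric's name and its reported magnitudes all imply
  intersection, which is what is implemented.)  Both-sets-empty is an error
  (0/0), not 0.
* Accuracy/sensitivity/specificity are one-vs-rest per class over in-mask
  voxels; background voxels inside the mask count toward the true negatives.
  A class absent from both truth and prediction reports missing (None)
  sensitivity, never 0.
* Volume fractions are normalized over GM+WM+CSF only (background excluded)
  and sum to 100% within rounding; absolute volume = voxel count × voxel
  volume / 1000 ml.
* CV% uses the sample (n−1) standard deviation, the convention for
  triplicate measurements; it is scale-invariant and zero for identical
  repeats up to float rounding of the mean.

## Problem sizes and defaults

End-to-end tests and the acceptance script use 64³ phantoms (262,144 voxels,
3 channels) — large enough that sample moments are tight (the 3%-noise σ
check passes at ±10%) while a full segmentation takes under a second; unit
tests use 32³.  Default pipeline configuration: ICA on, SVM cost 1 /
γ = scale, iteration tolerance 0.1%, cap 20, FLDA ridge 1e-6 (relative),
sphering ridge 0.  All randomness (phantom rendering, ICA initialization) is
explicitly seeded; the pipeline is bit-reproducible for fixed inputs and
config.

## Known limitations

* No partial-volume modeling or probabilistic tissue maps — hard labels only.
* No spatial regularization: very high noise produces salt-and-pepper errors
  that a Markov-random-field stage would smooth (deliberately out of scope).
* Seed quality matters in principle: patches must be class-pure; the
  robustness tests show volume estimates insensitive to *valid* alternative
  placements, not to mislabeled seeds.
* The clinical reproducibility tables of the motivating study (private
  patient data) cannot be recomputed; the package substitutes a
  property-based analogue (disjoint seed placements on the same phantom must
  change tissue volumes by < 1%).
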