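# trioseg

Voxel-based tissue segmentation of **multispectral brain MRI** — co-registered,
skull-stripped T1-weighted, T2-weighted and FLAIR (or PD) volumes — into gray
matter (GM), white matter (WM), cerebrospinal fluid (CSF) and background (BG),
entirely in the native coordinate space.  No atlas, no probability maps, no
spatial regularization: the only manual input is one small seed patch per class
on a single axial slice.  The package targets quantitative brain volumetry
(absolute tissue volumes in ml, intracranial volume fractions, reproducibility
as coefficient of variation) for neuroimaging researchers who need fast,
operator-robust measurements on clinical 3-D acquisitions.

## The algorithm

Each in-mask voxel is a feature vector **x** ∈ ℝ^C of its C channel
intensities.  The hybrid classifier couples three classical stages:

1. **Sphering / ICA.**  The features are whitened — the first two statistical
   moments removed, so E[**z**] = 0 and Cov(**z**) = I — and optionally rotated
   into statistically independent components, **s** = **W x** with mixing model
   **x** = **A s**.  This enhances the tissue contrast and makes the next stage
   insensitive to kernel hyperparameters.
2. **Seed SVM.**  An operator marks one 3×3 patch per class (9 voxels, 36
   samples for four classes) on one axial slice.  An RBF-kernel one-vs-one SVM
   (cost 1, γ = 1/(C·Var)) trained on those 36 samples labels every in-mask
   voxel of that slice, producing a large training pool from a tiny input.
3. **Iterative Fisher LDA (IFLDA).**  Fisher's discriminant maximizes the
   ratio of between- to within-class scatter,

       J(w) = (wᵀ S_B w) / (wᵀ S_W w),
       S_W = Σ_j Σ_{r∈C_j} (r−μ_j)(r−μ_j)ᵀ,
       S_B = Σ_j n_j (μ_j−μ)(μ_j−μ)ᵀ,
       S_T = S_W + S_B,

   yielding p−1 discriminant directions for p classes (generalized
   eigenproblem S_B w = λ S_W w).  Voxels go to the nearest class centroid in
   discriminant space; the freshly labeled volume becomes the next training
   set, iterated until fewer than 0.1% of labels change.

Evaluation implements the similarity index SI = 2|X∩Y| / (|X|+|Y|) (the Dice
coefficient), one-vs-rest accuracy/sensitivity/specificity, ml volumes and
GM/WM/CSF volume fractions, and CV% = 100·sd/mean across repeated measurements.

A synthetic phantom generator emulates the public simulated-brain (BrainWeb)
test grid — 1 mm isotropic multispectral volumes, four classes, noise at
0/1/3/5% of the brightest tissue mean, 0/20% multiplicative intensity
non-uniformity — so the whole pipeline is testable without any download.

## Worked example

Generate a 64³ phantom with 3% noise, segment it, and score it against its own
ground truth:

```sh
trioseg phantom --noise 3 --seed 7 --size 64 --out-dir ph
python -c "
from trioseg import io; from trioseg.phantom import PhantomSpec, default_seeds
from trioseg.types import BrainMask; import numpy as np
spec = PhantomSpec.load('ph/phantom_spec.yaml')
io.write_seeds(default_seeds(spec), 'ph/seeds.json')
io.write_mask(BrainMask(np.ones(spec.grid_shape, bool)), 'ph/mask.nii.gz')"
trioseg segment --channel ph/T1.nii.gz --channel ph/T2.nii.gz \
    --channel ph/FLAIR.nii.gz --seeds ph/seeds.json --mask ph/mask.nii.gz \
    --out-dir seg
trioseg evaluate --predicted seg/labels.nii.gz --truth ph/truth.nii.gz \
    --mask ph/mask.nii.gz --out-dir eval
trioseg volumes seg/labels.nii.gz --out-dir vols
```

which prints

```
segmented in 2 iterations (converged=True); labels in seg
     accuracy  sensitivity  specificity  similarity_index
CSF       1.0          1.0          1.0               1.0
GM        1.0          1.0          1.0               1.0
WM        1.0          1.0          1.0               1.0
```

and `vols/volumes_0.csv` holds the volumetry: GM 57.6 ml (54.1% of the
GM+WM+CSF volume), WM 23.9 ml (22.5%), CSF 25.0 ml (23.5%).  At this noise
level the four phantom classes are still well separated in channel space, so
the iterative discriminant reaches the exact labeling — every overlap metric
is 1.0.  `segment --export-models` additionally dumps the fitted sphering/ICA/
discriminant models as JSON for audit, and every subcommand writes a
`manifest.json` from which the run can be reproduced.

For the real simulated-brain benchmark (after downloading the raw T1/T2/PD
volumes and the crisp anatomical model into `data/brainweb/`):

```sh
trioseg reproduce-brainweb --data-dir data/brainweb --noise 3 --rf 0
```

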