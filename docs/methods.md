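# Methods

## Models

### Linear SVM

Both mapping methods use the standard soft-margin linear support vector
machine: minimise ½‖w‖² + C Σξᵢ subject to yᵢ(w·xᵢ − b) ≥ 1 − ξᵢ. The
decision value of a sample is w·x − b; ties (exactly 0) deterministically
predict class +1. C defaults to 1 and is exposed everywhere; the data are
always scaled to [−1, +1] per feature before training, so C = 1 is a
reasonable operating point and results are insensitive to moderate changes.

The solver is an in-package SMO working on the dual with maximal-violating-
pair selection (KKT tolerance 1e-8 for standalone fits, 1e-6 inside the
searchlight loops, where only decision signs matter). It operates purely on
Gram matrices. This matters for the searchlight: a sphere's Gram matrix is a
sum of per-voxel sample products, so convolving each pairwise product volume
with the binary sphere footprint yields the Gram matrices of *all* centres
at once, and label permutations — which change only y, never the data —
re-use the cached Gram field. Zeroing out-of-mask voxels before the
convolution is exactly equivalent to excluding them: a constant-zero feature
contributes nothing to any inner product. Unit tests verify bit-identical
maps against a naive per-centre feature-extraction path, and decision-value
agreement (1e-6) with both a direct QP solve and libsvm.

### Searchlight decoding

Spheres contain every voxel offset d with ‖d‖ ≤ r; r is interpreted in
voxel units or millimetres (anisotropic voxels are honoured by scaling each
axis by its physical size). Spheres are clipped to the mask — boundary
centres simply use fewer voxels; no minimum-size exclusion is applied, so
the map has no holes. Cross-validation enumerates all leave-2-out folds (one
test sample per class, n_A × n_B folds); `max_folds` subsamples folds
reproducibly for large sweeps. Feature scaling is fitted on all samples
before cross-validation, which mirrors the procedure this package models
(scaling precedes sphere construction); a consequence is a small optimistic
bias at very small sample sizes, negligible at the 15+15 samples used
throughout. Chance level for balanced data is 0.5.

### Feature weight mapping

PCA is computed by SVD of the column-centred data matrix; centring bounds
the rank by n − 1, which fixes the retained dimensionality to n − 1 = 29
components for 30 samples (the "last" component of the raw matrix carries no
variance after centring). Component scores are scaled to [−1, +1], the SVM
is trained once on all samples, and voxel weights are obtained by
back-projection through the orthonormal loadings after folding the score
scaling into the component weights (w_vox = L (w ∘ a), a = per-component
scale factor). The resulting map is the gradient of the decision function in
voxel space: positive weights push toward class A. Constant components
(scale factor 0) contribute nothing. FWM produces weights only — no
accuracies.

### Permutation inference

Permutations reshuffle the label vector, preserving the 15/15 balance;
identity and duplicate arrangements are excluded and everything is
reproducible from a seed. For SLD one permutation list is held fixed across
all searchlight locations (preserving spatial correlations); each
permutation's fold scheme is rebuilt on the permuted labels so every fold
again tests one sample of each class. For FWM permutations act at the
component level: the PCA and score scaling are computed once from the data
(they do not depend on labels) and only the SVM is re-solved.

Per-voxel empirical p-values use the conservative (b+1)/(m+1) estimator with
ties counting as exceeding, so p ∈ (0, 1] and no voxel can reach p = 0.
Accuracy maps are thresholded one-sided (upper tail); weight maps two-sided
(+1 when the upper-tail p ≤ α/2, −1 for the lower tail; if both tails pass
the smaller one wins, ties to +1). Permuted maps are thresholded against the
pooled ensemble including themselves (p = count/m); ranking each permutation
against only the others under the (b+1)/(m+1) convention yields the
identical number, so the two readings of the procedure coincide and no
option is needed.

Clusters are maximal 6-connected (face-connected) components; positive and
negative voxels cluster separately. Cluster sizes from all permuted
binarized maps are pooled — across signs — into one empirical cluster-size
null; each observed cluster's p is the (b+1)/(N+1) tail probability of its
size, and Benjamini–Hochberg step-up FDR at q = 0.05 selects the surviving
clusters. Pooling the signs doubles the null sample and is symmetric under
the null. The defaults n_perm = 1000 (mapping analyses) trade p-value
resolution (min p ≈ 1e-3) against cost.

## Synthetic data generator

Each of the 30 samples (15 per class) is a 66 × 22 × 22 volume of i.i.d.
N(0, 1) noise, smoothed with a separable Gaussian of FWHM 1 voxel
(σ = FWHM/√(8 ln 2), unit-sum kernel, nearest-edge replication so the noise
variance is flat to the boundary), after which a constant offset of 0.5
(in noise-SD units) is added inside the informative regions of the sample's
own class. Ground truth is three pairs of 6 × 6 half-cubes stacked above
(class A, +1) and below (class B, −1) the volume mid-plane: thickness 1 with
a 4-voxel gap (fine spread), thickness 2 with a 2-voxel gap (intermediate),
thickness 3 touching (coarse). Pairs are centred at x = 11, 33, 55, so the
three equal thirds along x each contain one pair; blocks are centred
in-plane. The gap is split symmetrically about z = nz//2 (upper block starts
at mid + ⌈gap/2⌉). Adding the offset after smoothing keeps the block edges
sharp, matching the boxy ground truth the evaluation counts against; the
exact block coordinates and the order of operations are recorded in the
serialised parameters so alternative layouts remain reproducible.

What the generator emulates: the low single-voxel contrast-to-noise regime
(offset 0.5 SD), slight intrinsic spatial smoothness, balanced two-class
designs, and graded coarseness of information spread. What it does not:
hemodynamics, anatomy, motion or physiological artefacts, inter-subject
variability, or spatially varying noise. Passing tests therefore demonstrate
the statistical behaviour of the pipelines under controlled conditions, not
performance on real acquisitions.

## Evaluation

Precision = TP/(TP+FP) and sensitivity = TP/(TP+FN) are counted over voxels
against the ground-truth support; a detected voxel of either sign inside any
block counts as a true positive. Per-coarseness curves restrict both the
detections and the truth to the volume third containing the pair (false
positives are counted region-wide, recorded in the output). Precision with
zero detections is undefined and stored as NaN. The default threshold grid
{0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5} spans the regimes
where each method operates best (around 0.001 for searchlight, 0.05 for
FWM). Sweeps reuse one permutation ensemble across thresholds, since only
the binarization/cluster stage depends on the threshold.

## Problem sizes

The package's own study sizes, chosen once: the headline corrected-FWM sweep
runs the full 66 × 22 × 22 volume with n_perm = 1000 over 5 seeds; null
calibration uses a 24 × 12 × 12 offset-0 volume with n_perm = 500 over 20
seeds; searchlight sweeps run on 18 × 14 × 14 crops centred on a single
half-cube pair (≥ 4-voxel margin around the pair, enough for the radius-3
sphere halo) with n_perm = 100 and a 15-fold cap. The cropped searchlight
configurations are scaled-down by design: the permutation loop re-solves
one SVM per centre, fold and permutation, and the crop keeps that product
in the millions rather than billions.

## Known limitations

- The searchlight Gram field is built by FFT convolution; entries agree
  with direct summation to ~1e-12, which can in principle flip a
  cross-validation prediction whose decision value is within that distance
  of zero. Not observed in practice; the naive engine exists for checking.
- Fold subsampling (`max_folds`) makes the accuracy lattice coarser
  (multiples of 1/(2·max_folds)), which coarsens searchlight p-values.
- With n_perm permutations the smallest attainable voxel p is 1/(n_perm+1);
  two-sided tests halve the usable tail. Threshold grids finer than that
  resolution detect nothing, by construction.
- The whole-volume linear SVM sees p ≫ n features; its weight map is the
  decision gradient restricted to the 29-dimensional span of the data, and
  voxelwise weight noise grows with volume size at fixed sample count.
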