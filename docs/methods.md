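# Methods

## The mapping model

The framework treats 3D disease mapping as tiled patch classification: the
masked lung region is cut into non-overlapping patches (stride = patch
size), each patch receives one of six texture labels, and labels are
broadcast back to voxels.  This trades boundary resolution for a simple,
auditable decision unit — a patch — to which uncertainty and saliency
estimates attach naturally.  Consequences of the design:

* every voxel of a tile inherits the tile's label, so class boundaries are
  quantized to the tile grid; the achievable voxel accuracy is bounded by
  the "majority-downsampled" truth (on the default phantom at 32×32×3 that
  ceiling is ≈ 83 %, and mapped profiles recover ground-truth disease
  ratios to well within 0.1);
* tiles that would overrun the volume are shifted inward so the last tile
  abuts the boundary; where two shifted tiles overlap, the later tile in
  raster order (slice-major, then row, then column) wins.  Tiles with less
  than `min_mask_fraction` (default 0.05) lung content are dropped and left
  unlabelled;
* a patch that straddles classes is, for training and evaluation purposes,
  labelled by the majority truth class among its lung voxels, ties broken
  toward the lower class id.  Whole-patch label assignment (rather than
  boundary interpolation) is a deliberate choice: it keeps the rebuild an
  exact inverse of extraction.

## Reference classifier

`models.build_denres_mini` constructs a small numpy network that mirrors the
dual-branch idea — a residual-style branch and a dense-connectivity branch
whose channel-concatenated features feed a convolution + average-pool head
(tagged `post_concat`, the layer Grad-CAM inspects) and a three-level
perceptron (256 → 64 → 6) with two Monte-Carlo dropout layers (p = 0.3).
Forward and backward passes are hand-written, which keeps the
activation/gradient taps for Grad-CAM, the rectifier rule for guided
backpropagation, and the dropout sampling for epistemic uncertainty all
explicit and unit-testable (backprop is verified against central finite
differences at 1e-6).

Training policy: seeded shuffle, 70/30 train/validation split, categorical
cross-entropy summed over each mini-batch (batch 32), plain SGD at a fixed
learning rate of 1e-4, 25 epochs, He-uniform initialization.  Because the
learning rate is fixed and small, inputs in [0, 1] are mapped through a
constant affine normalization to [−3, 3] inside the network; this scales
gradients so the fixed rate trains the separable six-class task to ≥ 90 %
held-out accuracy within 25 epochs.  The perceptron widths (256/64) are a
design choice; nothing downstream depends on them.

Any object implementing `ClassifierContract` (deterministic
`predict_proba`, a `post_concat` activation/gradient tap, optional guided
input gradients, optional stochastic mode) can replace the reference
network — adapters for externally pretrained backbones plug in at this
seam.

## Uncertainty estimators

*Aleatoric* (data) uncertainty is the Shannon entropy, in nats, of the
argmax-label frequencies over n = 21 test-time augmentations; the classifier
runs deterministically so only the input perturbation varies.  The TTA
family is rotation ±15°, shrink/scale ±10 %, additive Gaussian noise with
sd 1 % of the intensity range; shifts are excluded at test time so the patch
stays registered to its tile.  Frequencies use hard argmax votes (a
softmax-averaged variant is available behind `soft=True`).  H is 0 for
unanimous votes and ln 6 ≈ 1.79 at the uniform distribution.

*Epistemic* (model) uncertainty fixes the input and runs T = 21 forward
passes with the dropout layers active; reported are the mean softmax vector,
the per-class population variance (computed in a first-sample-anchored
streaming form that returns exactly zero when every pass agrees), and the
scalar variance at the argmax-mean class.  The aleatoric term is kept
separate from this variance rather than added into it, because the two are
analysed separately downstream; callers can sum them if a combined value is
wanted.

Per-patch scalars are broadcast to voxel maps exactly as labels are; the
conventional display clamps the red scale to [0, 0.30].

## Explainability

Grad-CAM weights the `post_concat` channel activations by the spatial mean
of the class-score gradient, rectifies, bilinearly upsamples to the patch
plane and max-normalizes.  Guided Grad-CAM multiplies in the
guided-backpropagation input gradient (negative gradients zeroed at every
rectifier), reduced to 2D by channel mean.

The generalized analysis runs PCA per class over all patch images
(PCA-Shape) and over all their Grad-CAM maps (PCA-GradCam) for k ∈
{4, 8, 16} components.  Depth-3 patches are reduced to 2D by channel mean
before PCA.  Component sign is fixed by making the largest-magnitude pixel
positive, so reports are reproducible.  Matching components are summarized
by the Pearson correlation and by the fraction of pixels whose centred
product `(s(x) − mean_s)(g(x) − mean_g)` falls above / below a ±1e-12
deadband — a decomposition of the correlation numerator into supporting and
opposing pixels.  A component is "correct" when supporting pixels outnumber
opposing ones under the **standard** orientation (high PCA-Shape intensity
marks structures of interest) and the rule flips under **inverted**; the
class verdict is a majority over components (configurable to any/all).
Orientation is an analyst input: nothing in the data itself says whether
bright shape structure is the region of interest or its complement, and no
automatic thresholding protocol is attempted.

On the phantom the positive/negative ratios often sit near 0.5/0.5: the
synthetic textures are spatially stationary, so shape components are
high-frequency patterns with little stable alignment to the smooth saliency
maps, and per-class verdicts are weakly determined.  Cross-k verdict
stability is therefore reported as a summary flag per class rather than
asserted as a property of the generator.

## Synthetic phantom

The generator emulates exactly what the pipeline needs and no more: two
ellipsoidal lungs inside a bright elliptical body, intensities in arbitrary
[0, 1] units (not calibrated HU), and six texture motifs chosen for distinct
(mean, variance) signatures — dark lightly-noisy parenchyma; a hazy raised
mean with smooth variation; haze plus a bright line lattice; bright cyst
walls around dark lumens; abnormally dark blobs; dense consolidation.
Gaussian noise (default sd 0.03) is added everywhere and intensities are
clipped.  The default study phantom is 160×160×9 voxels at 1×1×3 mm with
each lung split into three row bands, so all six classes occupy compact
patch-sized regions; a fractional-burden region type assigns an exact
fraction of lung voxels to a class for profile-arithmetic tests.

Balanced labelled patches are sampled at random positions (overlap allowed);
a sample must be majority-lung (`min_mask_fraction = 0.5`) and carries its
majority-truth label.  A `min_purity` filter can restrict sampling to
homogeneous single-texture patches — used when measuring texture
separability — but the training default is purity-free, so the classifier
sees the same boundary-straddling patch population the mapping stage
produces.  Training patches are drawn from a phantom preprocessed with the
same diffusion filter and normalization the pipeline applies at deployment;
skipping this produces a train/deploy intensity shift and visibly degraded
maps.

What passing on the phantom does **not** show: robustness to scanner and
dose variation, HU calibration, anatomical texture gradients, lesion shapes
that do not follow band geometry, or class imbalance as encountered in
patient cohorts.  The phantom establishes that the machinery — tiling,
learning, rebuild, uncertainty, explainability — is correct, not that the
reference network generalizes clinically.

## Preprocessing

Noise reduction is a per-slice Perona–Malik-type anisotropic diffusion
(conduction `1/(1 + (|∇I|/K)²)`, default K = 1.0, time step 0.125, 5
iterations); the explicit scheme requires time step ≤ 0.25 and is rejected
otherwise.  Normalization is per-volume min–max to [0, 1] (degenerate
constant volumes are an error).  Training augmentation follows the protocol
family: rotation ±15°, in-plane shifts up to 20 px, optional ZCA whitening.
ZCA is the symmetric whitening `U diag((λ+ε)^(−1/2)) Uᵀ` with the batch mean
re-added; it is distinct from the additive-noise TTA perturbation, and both
are exposed separately.  Geometric augmentation is a single bilinear affine
resample per depth slice (rotation, scale, shift composed), filled with the
patch minimum to avoid wrap-around artefacts.

## Evaluation

Label maps are scored over voxels labelled in both maps: macro-averaged
Jaccard/f1/recall/precision over the six classes, voxel accuracy, the
multiclass (Gorodkin) Matthews correlation coefficient, raw Hamming
disagreement, and RMSE over ordinal class indices (healthy = 0 …
unhealthy = 5).  The millimetre Hamming distance is defined here as
mismatch count × in-plane pixel spacing / number of evaluated slices — a
per-slice mismatch length.  This definition is recorded because the
quantity's construction is not standardized; values are not comparable
across datasets with different slice layouts.  Probability outputs are
scored with one-vs-rest AUC per class using midrank tie handling; classes
lacking both outcomes are reported as absent rather than failing.  All
implementations are cross-checked in the test suite against brute-force
confusion-matrix and O(n²) pairwise-AUC oracles.

## Determinism and numerics

Every stochastic step (phantom noise, sampling, weight init, shuffling,
dropout, TTA draws) is driven by an explicit seed; per-patch seeds are
derived from the global seed and the patch position so results do not
depend on batch partitioning.  Identical config + seed reproduces reports
byte for byte (timing excluded).  Known numeric edges: probabilities can
differ at ~1e-15 between batch sizes (BLAS summation order); the dropout
variance uses a shifted streaming form to return exact zeros; PCA and the
correlation ratios fix tie and sign conventions explicitly (argmax ties to
the lowest class id, component sign by largest-magnitude pixel, a ±1e-12
deadband around zero pixel contributions).

## Problem sizes

Default study sizes — a 160×160×9 phantom, 200 training patches per class at
32×32×3, 25 epochs, 21 TTA draws and 21 dropout passes per patch — were
chosen so a full study run (train + map + uncertainty + explainability)
completes in about a minute on one CPU core while leaving every estimator
with enough draws for stable statistics.

## Known limitations

* Lung segmentation is out of scope; the mask is an input (an Otsu
  threshold fallback exists for phantoms and simple scans only).
* The reference network is a topological analogue of the full-scale
  dual-branch architecture, not a reimplementation; no transfer learning
  from natural images is attempted.
* The positive/negative pixel-ratio decomposition and the per-slice
  millimetre Hamming distance are operational definitions made here; both
  are documented above precisely because alternative constructions exist.
* Verdict orientation must be supplied by the analyst; no automatic
  inference is attempted.
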