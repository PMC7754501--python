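# Methods

## Model and assumptions

The package treats segmentation of a FIB-SEM stack as independent
per-pixel binary classification (0 = pore, 1 = solid) followed by spatial
regularization. The core assumptions are:

* slices are aligned (rigid-body registration happens upstream) and share
  a single global intensity scale after 16-bit → [0, 1] conversion;
* the acquisition-induced intensity trend is near-linear along a single
  in-slice axis (x), so one least-squares line fitted to the plane-averaged
  profile captures it. Subtracting the line and adding back its mean keeps
  the volume's spatial mean unchanged and leaves genuine porosity-driven
  intensity fluctuations intact — the reason moment-matching slice
  normalization is deliberately not used;
* shine-through makes the class of a pixel depend on its neighbouring
  slices, so the feature vector spans 11 slices even though all smoothing
  is 2D within slices.

### Feature space

Per pixel: Gaussian-smoothed intensities at σ ∈ {0, 1, 2, 4, 8, 16, 32,
64, 128} px evaluated at slice offsets −5 … +5, i.e. 99 features. Kernels
are sampled Gaussians truncated to full width 4σ+1 (2σ+1 at the largest
scale, to bound boundary effects) and renormalized to sum exactly to 1.
Renormalization is what makes constant images fixed points and the map
affine-equivariant, `features(a + b·I) = a + b·features(I)` — the
property that licenses applying intensity augmentation directly to stored
feature vectors. Filtering is separable (two 1D passes), which agrees
with dense 2D convolution to ~1e-15 and costs O(σ) per pixel instead of
O(σ²).

Boundary handling is mirror reflection *without* repeating the edge
sample (slice −1 ≡ slice 1), both for in-slice filtering and for slice
offsets beyond the stack; the edge-repeating variant is available via
`ScaleSpaceConfig(boundary="reflect")`. For whole-volume prediction the
mirror extension is applied to the already-filtered volumes, not by
re-filtering extended raw data.

### Sampling

Annotation regions are squares (default 256 px, neighbourhood 384 px ×
7 slices) placed uniformly over all positions where the neighbourhood
fits. Splits are by region, never by pixel: 60 % train / 20 % val /
20 % test. From each split's squares a class-balanced 2.5 % of pixels is
drawn without replacement, pooled across regions (per-dataset); the
fraction is kept small because neighbouring pixels are strongly
correlated and add little information. The balanced target count is
`round(fraction × n_pixels)` forced even, half per class; a class too
small to supply its half raises an error rather than silently sampling
with replacement.

On small synthetic volumes, randomly placed squares would frequently
overlap, leaking labelled pixels between splits; the synthetic dataset
builder therefore places squares without mutual overlap (rejection
sampling). On production-scale stacks overlap is improbable and plain
random placement is the default.

### Classifier

Bootstrap forest of CART trees, Gini impurity, minimum leaf size n_mls.
The feature subspace (n_f columns) is drawn **per tree**, not per split —
each tree sees the same candidate features at every node. The score is
the average *hard* vote, so scores are quantized to multiples of 1/n_t
and an odd n_t makes thresholding at 0.5 tie-free. Both choices differ
from common library defaults (per-split subsampling, averaged leaf
probabilities) and are pinned by tests; `per_tree_features=False`
switches to per-split mode. Individual trees are scikit-learn
`DecisionTreeClassifier`s; the ensemble logic (bootstrap, per-tree
subspace, vote aggregation, column-map bookkeeping) is this package's.

Defaults n_t = 151, n_f = 28, n_mls = 14 are the best configuration found
with augmented training data; random search draws n_f ∈ [10, 40] and
n_mls ∈ [10, 50] uniformly and, when augmenting, σ_a and σ_b from an
exponential distribution with mean 0.01. Increasing n_t beyond 151 gives
no significant improvement, only cost.

### Postprocessing

Two passes of within-slice Gaussian smoothing + thresholding with shared
(σ_xy, T). The second pass smooths the *binarized* result of the first
(the reading "re-smooth the raw score" is available via
`second_pass_on="score"`). Thresholding uses ≥, so exact ties go to
solid. Tuning maximizes validation mIoU with Nelder–Mead over
(σ_xy, logit T) starting at (2.0, logit 0.5); the logit keeps T in (0, 1)
and negative σ proposals are clamped to 0. The tuned result is never
worse than the start point (the start is returned if the simplex ends
below it). T < 0.5 is expected on real data: training samples are
class-balanced while true porosity is well under 50 %. Tuned reference
values for the EC/HPC film stacks are σ_xy = 2.796 px, T = 0.4495, and
these are the `PostprocessConfig` defaults.

Small-object removal reassigns connected components *strictly* smaller
than 100 voxels (a 100-voxel component survives), pore phase first, then
solid on the modified mask; labelling is 3D 6-connected by default
because the output is a volume, with 26-connected and per-slice 2D
options (the cleaning order and connectivity are configurable and
logged since either reading is defensible).

### Metrics

Per-class IoU with the empty-union convention IoU = 1 when the class is
absent from both masks (relevant only for tiny regions); mIoU as the
two-class mean; Dice (identically 2·IoU/(1+IoU)); accuracy; binary
cross-entropy with scores clipped to [1e-12, 1−1e-12] and the
conventional leading minus sign, so it is non-negative. Porosity
confidence intervals use the normal approximation mean ± 1.959964·sd/√n
across regions; at n = 100 regions Student-t would differ in the third
decimal. The global-threshold baseline scans a fixed grid of step 1/1024
over the pooled train+val regions via per-class cumulative histograms and
returns the first maximizer of mIoU.

## Synthetic data: what it emulates, what it does not

`generate_structure` thresholds a periodic 3D Gaussian random field
(white noise smoothed at the correlation length) at the empirical
quantile of the target porosity — porosity is exact to one voxel, and
ground truth is known, so every metric has an unambiguous reference.

`render_fibsem` models three artifacts:

* **Shine-through**: a pore voxel with its first backing solid voxel d ≥ 1
  slices deeper (along +z, the unmilled material) renders at
  `pore_floor + (solid_level − pore_floor)·exp(−(d−1)/λ)`. The decay is
  anchored at d = 1 so a pore with solid on the very next slice is
  indistinguishable from solid in that slice — this is what makes the
  pore/solid histograms genuinely overlap and global thresholding fail,
  the central difficulty the generator exists to reproduce. λ = 0
  disables the artifact. The ray model casts straight along z with no
  lateral blur of the subsurface signal — a deliberate simplification.
* **Gradient**: an additive linear ramp `gradient_slope · x`
  (default 8e-4 per px ≈ 0.1 intensity across a 128-px volume).
* **Noise**: additive i.i.d. Gaussian (default sd 0.05), then clipping
  to [0, 1].

Defaults: solid_level 0.75, pore_floor 0.15 (bracketing mid-range with
headroom for gradient and noise before clipping), correlation length
4 px (pore/strut sizes of order tens of pixels, several slices thick —
comparable in proportion to the imaged films).

Not modelled: curtaining, charging, redeposition, shadowing, detector
physics, partial-volume edges, anisotropic voxels' effect on the point
spread, and real phase-separated morphology (a thresholded GRF is
morphologically simpler than a spinodal structure). Passing tests on
synthetic volumes therefore demonstrate that the pipeline's machinery is
correct and that it beats thresholding *when shine-through is the
dominant artifact* — not that real-data accuracy will match.

## The built-in recovery study

`fibsemseg.study.run_study` is the package's end-to-end demonstration,
sized to run in well under a minute on one CPU: three 128 × 128 × 40
volumes at porosities 0.22 / 0.30 / 0.45 (the nominal compositions of
the three film samples), λ = 3 slices, noise sd 0.05; 64-px regions with
96 px × 7 slice neighbourhoods; 20 training regions across the three
volumes (7 + 7 + 6) plus 2 validation and 2 test regions per volume
(preserving the 60/20/20 ratio approximately); a 51-tree forest with
n_f = 30, n_mls = 10 (leaf size scaled down with the ~2000-row training
sample, n_f kept inside the standard search range). It reports recovered
whole-volume porosities, pooled and per-volume test mIoU, the tuned
postprocessing parameters, and the per-volume global-threshold baseline.
Typical results: porosity errors below one percentage point, test mIoU
≈ 0.98–0.99 versus baseline ≈ 0.88–0.95.

## Numerical and design notes

* All randomness flows from a master seed; per-stage seeds are derived
  by SHA-256 hashing of the stage name so adding a stage does not shift
  other stages' streams. Training, prediction and the study are
  bit-reproducible under a fixed seed.
* Gradient fitting regresses the per-x plane means, which is
  algebraically identical to regressing all voxels on x but O(nx).
* Correction clips to [0, 1] *after* the subtraction; clipping (rather
  than rescaling) preserves voxel values the gradient never touched.
  Diagnostic callers can disable clipping to verify the exact
  idempotence and mean-preservation identities.
* Full-region evaluation pools pixels across regions (per split) rather
  than averaging per-region metrics; per-region values remain available
  for porosity confidence intervals.
* Model artefacts serialize the feature column map and per-tree feature
  subsets; prediction refuses feature matrices whose column map differs,
  preventing silent feature permutation.

## Known limitations

* Prediction materializes all filtered volumes in memory (9 × the volume
  size); production-scale stacks (> 10⁹ voxels) need tiled filtering,
  which the API's slice-batched scoring anticipates but does not
  implement.
* The vote semantics ("average hard vote") and per-tree feature subspace
  are fixed by design; averaged leaf probabilities would give smoother
  scores but break the quantization invariant.
* The CLI's `train`/`search`/`learning-curve` commands currently drive
  synthetic study configurations; real-data training uses the library
  API (`Dataset` + `run_training`) with externally produced region
  labels.
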