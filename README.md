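# fibsemseg

Random-forest segmentation of FIB-SEM nanotomography stacks of porous
films, with 2.5D scale-space features, class-balanced sampling,
feature-space intensity augmentation, smooth-threshold postprocessing,
IoU-based evaluation — and a synthetic shine-through volume generator so
the entire pipeline can be exercised and validated without microscope
data.

## The problem

FIB-SEM tomography alternates ion-beam milling with electron imaging of
the exposed cross-section, producing a stack of grayscale slices of a 3D
microstructure. For *porous* materials (here: phase-separated polymer
films whose water-soluble phase has been leached out, leaving a pore
network), segmentation into pore and solid is hard because of the
**shine-through effect**: solid material *behind* the current
cross-section is visible through open pores, so the pore and solid
intensity histograms overlap and no global threshold separates the
phases. Slices are effectively 2.5D. An additional near-linear intensity
gradient along one in-slice axis comes from position-dependent detection
efficiency.

## The method

1. **Preprocess** — convert 16-bit data to [0, 1]; fit a least-squares
   line to the x intensity profile (mean over each y–z plane), subtract
   it and add back its mean.
2. **Features** — for each pixel, Gaussian-smoothed intensities at scales
   σ = 0, 1, 2, 4, 8, 16, 32, 64, 128 px (filter width 4σ+1, 2σ+1 at the
   largest scale; σ = 0 is the raw value), sampled in the pixel's slice
   and the five slices on either side: 9 × 11 = 99 features. Smoothing is
   strictly within-slice; the slice context is what lets the classifier
   see through the shine.
3. **Sampling** — annotation happens on square regions picked at random
   positions/slices; regions are split 60/20/20 into train/val/test, and
   a class-balanced 2.5 % of the square pixels is drawn per split.
   Optional augmentation replaces each training vector f by a + b·f with
   a ∼ N(0, σ_a), b ∼ N(1, σ_b) — valid in feature space because all
   features are unit-sum linear filters.
4. **Classifier** — a forest of n_t (odd, default 151) Gini decision
   trees, each trained on a bootstrap replica restricted to its own n_f
   random feature columns; the score is the average hard vote,
   interpretable as P(solid). Hyperparameters (n_f ∈ [10, 40],
   n_mls ∈ [10, 50], augmentation σ's ∼ Exp(0.01)) are tuned by random
   search on validation mIoU.
5. **Postprocess** — within-slice Gaussian smoothing of the score volume
   and thresholding, applied twice with the same (σ_xy, T) tuned by
   Nelder–Mead on validation mIoU, then removal of connected components
   smaller than 100 voxels from both phases.
6. **Evaluate** — per-class IoU, mIoU, accuracy, Dice, binary
   cross-entropy, porosity with normal-approximation confidence
   intervals, and an optimized global-threshold baseline for comparison.

## Worked example

Everything below is synthetic and reproducible (fixed seeds). The
generator builds a two-phase Gaussian-random-field structure with exact
porosity control and renders it with shine-through (a pore pixel with
solid d slices behind it brightens by exp(−(d−1)/λ) of the pore–solid
contrast), an x gradient, and noise:

```python
import fibsemseg as f

syn = f.SyntheticConfig(dims=(128, 128, 40), target_porosity=0.30,
                        shine_decay_depth=3.0, noise_sd=0.05, seed=7)
structure, image = f.simulate(syn)
image = f.correct_gradient(image)

thr, m = f.optimize_global_threshold(image.data, structure)
print(f"global threshold {thr:.3f} reaches mIoU {m:.3f}")
```

```
global threshold 0.664 reaches mIoU 0.927
```

Thresholding tops out well below perfect — the shine-through overlap at
work. The full pipeline (20 annotated 64 px regions across three such
volumes at porosities 0.22/0.30/0.45, a 51-tree forest, tuned
postprocessing) is packaged as `fibsemseg.study.run_study`:

```python
from fibsemseg.study import run_study

r = run_study(seed=1)
print({k: round(100 * v, 2) for k, v in r.porosity_recovered.items()})
print(f"test mIoU {r.test_miou:.4f}")
print({k: round(v['test_miou'], 4) for k, v in r.baseline.items()})
```

```
{'phi22': 21.87, 'phi30': 30.01, 'phi45': 45.27}
test mIoU 0.9906
{'phi22': 0.9064, 'phi30': 0.8961, 'phi45': 0.9501}
```

The recovered porosities sit within a fraction of a percentage point of
the generated 22/30/45 %, and the forest's test mIoU beats the
per-volume global-threshold baseline by a wide margin.

A CLI wraps the same functionality
(`fibsemseg simulate | preprocess | train | search | predict | evaluate |
learning-curve`); see `fibsemseg --help`.

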