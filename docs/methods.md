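# Methods

`pkdvol` implements a fully automated pipeline for segmenting polycystic
kidneys on axial abdominal CT and quantifying total kidney volume (TKV),
together with the statistical machinery needed to validate such a pipeline
against reference segmentations and a synthetic phantom generator that makes
the whole chain testable end to end without clinical data.

## The segmentation model

The segmentation network is a slicewise encoder-decoder fully convolutional
network. The encoder follows the first 10 convolution layers of the VGG-16
layout — blocks of (2×64, 2×128, 3×256, 3×512) filters, every convolution
3×3 with 1-pixel padding, each followed by batch normalization and ReLU —
with 2×2/stride-2 max-pooling between blocks. Each pooling layer records the
argmax location within every 2×2 window (ties resolve to the first position
in row-major scan order). The decoder mirrors the encoder: index-driven
unpooling places activations back at their recorded positions and
deconvolution stacks (3×3, stride 1, padding 1 — with this geometry a
transposed convolution is an ordinary convolution with a flipped kernel, so
we implement it as one) refine the upsampled maps; the last deconvolution of
each decoder stage steps the channel width down to the next-shallower
block's width. A final 1×1 convolution maps the features to two class maps
(kidney / non-kidney) and a per-pixel softmax yields foreground
probabilities. Training minimizes mean per-pixel multinomial cross-entropy
under AdaGrad (learning rate 1e-4, weight decay 5e-4, batch size 8, Xavier
initialization) with the training slices reshuffled every epoch.

The whole engine — convolution via im2col and BLAS matrix products, batch
normalization with running statistics frozen at evaluation, pooling with
indices, unpooling, and the AdaGrad update — is implemented in numpy with
explicit backward passes (`pkdvol.nn`). Gradient correctness is guarded by
central-difference checks in the test-suite.

### Scaled profiles

`NetworkSpec.width_multiplier` scales every channel count, and the input
size is free as long as it is divisible by 2^4. Two standing profiles:

* **clinical profile** — 224×224 input, full widths (the configuration the
  recipe above was designed for; training it is a GPU-scale job);
* **desk profile** — 64×64 input, width multiplier 0.25 (channels
  16/32/64/128, ~0.96 M parameters). The complete
  train-predict-evaluate loop runs on one CPU in minutes; this is the
  profile the test-suite and the acceptance script exercise.

The desk profile keeps AdaGrad, weight decay, batch size and initialization
but raises the learning rate to 0.03 (`pipeline.desk_training_config`).
AdaGrad's effective step shrinks with the accumulated squared gradients, so
a rate tuned for ~10^5 iterations over 48 000 slices moves a freshly
initialized network imperceptibly within a few hundred iterations; 0.03 was
picked from a coarse sweep on a 10-slice overfit task as the smallest rate
that converges within the desk iteration budget (~500 iterations).

After the optimization loop, `train` replaces the batch-norm running
statistics with the average batch statistics from one deterministic sweep
over the training set ("precise" batch-norm recalibration). In short runs
the exponential running estimates (momentum 0.1) lag behind the final
parameters, which systematically mis-normalizes evaluation-mode forward
passes; the recalibration sweep removes that lag without touching any
learned parameter.

## Preprocessing and augmentation

Each slice is resampled from the acquisition matrix (512×512 clinically,
64×64 for desk phantoms) to the network input size with bicubic
interpolation — nearest-neighbour for label maps, which keeps them binary —
then intensity-normalized to [0, 255] (affine, min→0, max→255; a constant
slice maps to zeros with a warning). The scalar grand mean over all training
pixels is subtracted at train and test time. The mean is a scalar rather
than a per-pixel image so that it transfers across resolutions.

Two augmentation branches triple the training set (originals kept, two
variants per slice — the only multiplicity consistent with tripling 16 000
slices to 48 000):

1. **rigid shift** — image and label translated identically by a uniform
   draw in ±`max_shift_px` per axis (x = column, y = row), vacated borders
   filled with 0;
2. **non-rigid deformation + intensity variation** — a smooth random
   displacement field (Gaussian-smoothed white noise, scale
   `deform_grid_sigma_px`, peak magnitude `deform_alpha_px`) warps image
   (bicubic) and label (nearest-neighbour) identically, then a smooth
   multiplicative field 1 ± `intensity_field_amplitude` (scale
   `intensity_field_scale_px`) modulates the image only.

Magnitudes at 224-pixel resolution default to shift ≤ 20 px, deformation
sigma 12 px / amplitude 10 px, intensity ±10% at 50 px scale — moderate,
label-preserving perturbations; the desk profile scales them by 64/224
(shift ≤ 6 px, sigma 4 px, amplitude 3 px, intensity scale 14 px). These
magnitudes are free parameters of the method; the augmentation law (count
tripling, identical geometric transform for image and label, binary labels
preserved) is what the tests pin down.

## Post-processing and volumetry

Foreground is every pixel with probability strictly greater than the
operating threshold (default 0.5). The operating point can be re-derived
from validation data with `select_threshold`, which scans a candidate grid,
pools pixelwise confusion counts, reports sensitivity, specificity,
accuracy, precision, F1 and Youden J = sensitivity + specificity − 1, and
selects the J-maximizing candidate (ties resolve toward 0.5). Predictions
are resampled back to the acquisition matrix with bicubic interpolation of
the binary map, re-binarized at 0.5, then cleaned per slice by a binary
closing with a disc structuring element (radius 3 px at 512 resolution,
1 px at desk resolution) followed by removal of connected components
smaller than `min_component_px` (50 px at 512, 8 px at desk) — closing
fills interior holes but cannot remove isolated islands, hence the separate
component filter. TKV is pixel-count volumetry:

    TKV [mL] = Σ_slices (foreground pixels × spacing_x × spacing_y ×
               slice thickness) / 1000,

with both kidneys pooled in a single foreground class.

## Agreement statistics

All comparisons use the convention automated − true. For masks, the Dice
similarity coefficient DSC = 2|A∩B|/(|A|+|B|), with DSC(∅,∅) ≡ 1 (perfect
agreement on absence). For paired TKVs:

* **Lin's CCC** with population (1/n) moments; the 95% CI applies Lin's
  asymptotic standard error on the Fisher-z scale.
* **Bland-Altman** mean difference and limits of agreement mean ± 1.96·SD
  (sample SD), in mL and in percent of the pairwise mean (pairs with zero
  pairwise mean are excluded from percentage mode).
* **Repeated-measures COV**: 100 · sqrt(mean per-pair variance) / grand
  mean, with per-pair sample variance (a−b)²/2 — the root-mean-square
  within-pair SD convention.
* **MPE / MAPE / RMSE / RMSPE** on percentage errors 100·(auto−true)/true.
* **Spearman ρ** (average ranks for ties) and the **Wilcoxon signed-rank
  test** (zero differences dropped; exact null for ≤ 25 pairs, normal
  approximation with continuity correction above), both via scipy.

Cross-validation partitions sort cases by ascending TKV and deal each
consecutive block of k cases randomly one-to-a-fold, so every fold samples
the full TKV range; fold sizes differ by at most one (242 cases → 80/81/81).

## Occlusion importance maps

A square of constant intensity (default side = 1/7 of the image, stride =
half the side, fill 0 after normalization — applied before mean
subtraction) slides over a slice; at each position the model re-predicts
and the map records the drop in DSC against the reference mask relative to
the unoccluded prediction. For a model that has learned the anatomy, the
mean DSC drop over kidney-overlapping occluder positions exceeds the mean
over positions at least two occluder widths away from the mask.

## The phantom generator

`pkdvol.phantom` builds seeded synthetic abdomens: an elliptic body
cylinder, a liver ellipsoid that may contain dark look-alike cyst blobs
(never part of the kidney mask), and two laterally separated kidneys, each
an ellipsoid carrying 4–18 embedded spherical cysts whose intensities are
bimodal — dark fluid-filled (~400) and bright hemorrhagic (~2200) against
parenchyma ~1500 on an abstract [0, 4095] scale — plus additive Gaussian
acquisition noise. Geometry and noise use independent sub-seeds, so masks
are bit-reproducible under noise sweeps. Kidney size can be driven either
by a field-of-view fraction or by a target TKV (ellipsoid semi-axes solved
from the volume at a fixed aspect ratio); cohort generation places target
TKVs at bin mid-points across the requested range, so realized volumes span
it approximately uniformly. The stored `true_tkv_ml` is by construction
exactly the pixel-count volumetry of the mask.

What the phantom does **not** emulate: Hounsfield calibration, contrast
phases, partial-volume blur, scanner artifacts, anatomical variability of
organs other than the two kidneys and liver, and respiratory/positioning
differences between acquisitions. Passing desk-scale tests therefore
demonstrates that the pipeline's machinery (augmentation law, optimization,
volumetry, statistics, occlusion analysis) is correct and that the method
can learn cyst-laden kidney morphology against a confounding liver — it
does not certify clinical-grade accuracy on real CT.

## Problem sizes used in tests

Desk phantoms are 128×128×24 voxels at 1.5×1.5 mm pixels and 2.5 mm slices
(192 mm field of view) with a flattened kidney aspect (0.90, 0.90, 0.55)
so that cohort TKVs up to ~200 mL fit the 60 mm slab. The acquisition
matrix is deliberately finer than the 64×64 network input: the desk
pipeline then exercises the same coarse-predict / bicubic-restore
structure as the clinical 512 → 224 → 512 configuration, and evaluation
happens at the native matrix where boundary quantization does not dominate
the Dice coefficient. Desk post-processing uses closing radius 2 px and a
20 px minimum component at the 128 matrix. The end-to-end check trains the
desk network for ≤ 500 iterations on ~216 augmented slices from 3 phantoms
(TKV 60–160 mL) and evaluates on 10 held-out phantoms; statistics are
validated on 50 random 20-case cohorts against brute-force implementations
at 1e-9.

## Known limitations

* The numpy engine targets clarity and desk-scale speed, not GPU-scale
  training; the clinical profile is configuration-complete but not trained
  here.
* Decoder hyper-parameters (deconvolution kernel/stride, decoder widths)
  follow the mirrored design described above; other reasonable choices
  exist.
* Left/right kidneys are not separated; liver-cyst false positives are the
  method's acknowledged failure mode and are deliberately present in the
  phantom.
* The Wilcoxon/Spearman p-values assume independent cases.
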