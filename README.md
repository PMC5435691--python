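# pkdvol

Automated segmentation of polycystic kidneys on abdominal CT and total
kidney volume (TKV) quantification.

In autosomal dominant polycystic kidney disease (ADPKD) the kidneys are
progressively enlarged by fluid-filled cysts, and TKV — both kidneys
combined, in millilitres — is the accepted imaging biomarker of disease
progression. Measuring it by manual slice-by-slice contouring takes an
expert ~30 minutes per acquisition. `pkdvol` implements a fully automated
alternative: a slicewise encoder-decoder fully convolutional network
(VGG-16-style 10-layer encoder with batch normalization; decoder of
index-driven unpooling and deconvolution layers; 1×1 convolution to
kidney/background class maps) followed by thresholding, bicubic restoration
to the acquisition matrix, morphological cleanup, and pixel-count
volumetry:

    TKV [mL] = Σ_slices (foreground pixels · spacing_x · spacing_y · slice thickness) / 1000

The package also provides the complete validation battery used for such
pipelines — Dice similarity coefficient (DSC), Lin's concordance
correlation coefficient (CCC) with 95% CI, Bland-Altman limits of
agreement, repeated-measures coefficient of variation, MPE/MAPE/RMSE/RMSPE,
Spearman ρ, Wilcoxon signed-rank — plus occlusion-based ΔDSC importance
maps, TKV-stratified k-fold partitioning, and a seeded synthetic phantom
generator (cyst-laden bilateral kidneys, a liver with look-alike cysts,
acquisition noise) so the entire chain is testable end to end without
clinical data. The network engine (convolution, batch norm,
pooling-with-indices, unpooling, AdaGrad, backprop) is implemented in
numpy; everything runs on a plain CPU at desk scale.

Audience: researchers in medical image analysis who need a transparent,
dependency-light reference implementation of this class of pipeline, and
anyone who needs the agreement-statistics battery on its own.

## Worked example

Train the desk profile (64×64 network input, 0.25 channel width) on three
synthetic phantoms and evaluate on ten held-out phantoms:

```python
from pkdvol import pipeline, phantom

tp = pipeline.train_phantom_segmenter(seed=1, n_train_cases=3,
                                      tkv_range_ml=(60, 160),
                                      n_iterations=500)
test = phantom.generate_cohort(pipeline.desk_phantom_spec(seed=101),
                               10, (60, 160))
report = pipeline.evaluate_on_cohort(tp.segmenter, test)
print(f"DSC {report.dsc_mean:.3f} ± {report.dsc_sd:.3f}   "
      f"MAPE {report.mape_pct:.1f}%   CCC {report.ccc:.3f}")
```

```
DSC 0.862 ± 0.029   MAPE 10.3%   CCC 0.809
```

Read: on held-out phantoms the automated masks overlap the ground truth at
a mean Dice of 0.86 and the automated TKV deviates from the true TKV by
10% on average, with a mild systematic under-segmentation (the
concordance of the two volume series is 0.81; Spearman ρ 0.98). Numbers
are for this seed; training is stochastic.

The same pipeline is scriptable from the shell:

```bash
pkdvol simulate --n-cases 5 --seed 1 --out cohort/
pkdvol train    --data cohort/ --iterations 500 --seed 1 --out model.ckpt.npz
pkdvol predict  --model model.ckpt.npz --in cohort/phantom-0001_image.nii.gz --out pred/
pkdvol evaluate --model model.ckpt.npz --truth cohort/ --out report/
pkdvol occlude  --model model.ckpt.npz --in cohort/phantom-0001_image.nii.gz \
                --mask cohort/phantom-0001_mask.nii.gz --slice 12 --out occ/
```

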