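# brainseg

Tissue segmentation for 3-D T1-weighted brain MRI: every voxel of the brain
is assigned to cerebrospinal fluid (CSF), gray matter (GM) or white matter
(WM).  The package is aimed at neuroimaging researchers who need a
self-contained, reproducible segmentation chain — and at method developers,
who get a synthetic-phantom benchmark with ground truth so every stage can
be tested without downloading reference datasets.

## Method

The chain combines an intensity model with a texture-driven classifier:

1. **Brain extraction** — Otsu foreground split, histogram peak location,
   mask threshold `t_m = μ_GM − α σ_GM`, binary opening with a radius-3
   spherical element (cuts the thin brain–skull connections), largest
   connected component, dilation, and `I₂ = I₁ · M₁`.
2. **Bias-field correction** — the smooth multiplicative field `f` in
   `v(x) = u(x) f(x)` blurs the log-intensity histogram by a kernel `F`;
   the correction iteratively sharpens the histogram by Wiener
   deconvolution, maps voxels to `E[u|v]`, and smooths the residual into a
   field estimate.
3. **Histogram segmentation** — a three-Gaussian model

       p'(i; v) = Σₖ pₖ exp(−½ [(i − μₖ)/σₖ]²),  k = 1..3  (C1=CSF, C2=GM, C3=WM)

   is fitted to the gray-level histogram by Levenberg–Marquardt,
   `v* = argmin Σᵢ [p(i) − p'(i; v)]²`, initialized from a kernel density
   estimate; voxels take the maximum-likelihood class, and low
   likelihood-ratio or boundary voxels are flagged *ambiguous*.
4. **Texture + SVM refinement** — 130 features per voxel of interest
   (13 Haralick statistics × mean/SD over 13 directions × distances 1–5
   from 3-D co-occurrence matrices in a 21³ window), reduced by stepwise
   discriminant analysis (Wilks' Λ, partial-F entry/removal), feed
   one-vs-rest soft-margin RBF SVMs (C = 100, 10 000 training voxels per
   image) that iteratively relabel the ambiguous voxels.
5. **Evaluation** — kappa index (algebraically the Dice coefficient
   `2|S₁∩S₂|/(|S₁|+|S₂|)`) and Jaccard per tissue against ground truth.

A phantom generator emulates simulated-MRI benchmarks (three tissue classes
with T1 ordering, Rician noise as % of the WM mean, a smooth multiplicative
bias field, a skull-like distractor attached by thin bridges) so the whole
chain is testable offline.  See `docs/methods.md` for models, parameter
defaults and limitations.

## Worked example

Segment a 96³ phantom at 5% noise and 20% bias and score it against its
own ground truth:

```python
from brainseg import PipelineConfig, run_pipeline
from brainseg.phantom import PhantomSpec

spec = PhantomSpec(noise_pct=5, bias_pct=20, seed=5)
result = run_pipeline(spec, PipelineConfig(seed=5), out_dir="run")
print(result.report.to_frame()[["kappa", "jaccard"]])
```

prints (kappa is the Dice overlap with the ground truth; 1.0 is perfect):

```
        kappa   jaccard
CSF  0.959930  0.922947
GM   0.975664  0.952485
WM   0.987233  0.974788
```

so after the full chain 98.7% (Dice) of white matter and 97.6% of gray
matter agree with the phantom's anatomy.  `run/` contains the corrected
volume, brain mask, initial and final label maps, the ambiguous-voxel
mask, the trained classifier, the overlap report and a JSON manifest with
every fitted parameter (Otsu threshold, histogram peaks, mixture
parameters, selected features, timings).

The same pipeline runs from the shell:

```bash
brainseg run --phantom-noise 5 --phantom-bias 20 --seed 5 --out-dir run
brainseg run --in subject_T1.nii.gz --out-dir out          # real volume
brainseg phantom --noise-pct 3 --bias-pct 20 --seed 1 --out-prefix ph
brainseg evaluate --pred out/labels_final.nii.gz --truth ph_truth.nii.gz
```

Individual stages are exposed as `correct-bias`, `extract-brain`,
`segment-histogram`, and as library functions (`correct_bias`,
`extract_brain`, `fit_mixture`, `extract_features`, `sda_select`, `train`,
`refine`, `evaluate`).

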