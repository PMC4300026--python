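# Methods

`brainseg` segments a T1-weighted brain MR volume into cerebrospinal fluid
(CSF), gray matter (GM) and white matter (WM) with a hybrid
statistical/machine-learning chain: intensity modeling does the bulk of the
work, and a texture-driven SVM revises only the voxels the intensity model
is unsure about.  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic phantom does and does not
establish.

## Pipeline model, stage by stage

**Gray-level convention.** All histogram stages operate on an integer
gray-level volume, obtained by linear rescaling to `[0, W-1]` with
`W = 256`.  Rescaling is explicit (`rescale_to_gray`), never implicit.

**Foreground split.** Otsu's threshold `t_Otsu` maximizes the between-class
variance of the gray-level histogram; foreground is strictly `> t_Otsu`
(ties go to background).  On T1 head images this removes the air background
and, usually, the darkest CSF — the tissue model below is designed for
that.

**Brain extraction.** The stage assumes the brain touches skull/scalp only
through thin, mostly-dark connections and is the largest connected
component.  The foreground histogram is smoothed with a Gaussian kernel
(bandwidth 2 gray levels) and its modes located by prominence; with three
modes they are (CSF, GM, WM) in gray-level order, with two the CSF location
falls back to the midpoint between the first occupied level and the valley
left of GM (the CSF class often has no peak after the Otsu split — this is
the *normal* path, not an error path).  The binary mask `I1 > t_m` with
`t_m = μ_GM − α·σ_GM` is opened with a digitized sphere of radius 3 voxels
(cutting the thin bridges), reduced to its largest 26-connected component,
and dilated three times with the same element; `I2 = I1 · M1`.

*Why α = 2 (not 1):* `σ_GM` is half the GM mode's FWHM.  At realistic noise
an `α = 1` threshold sits about one standard deviation inside the GM
distribution, so ~16% of GM voxels drop out of the mask; a radius-3 opening
then destroys the porous cortical shell (measured mask Dice 0.85 on the
default phantom).  `α = 2` keeps ~98% of GM while CSF remains more than 4σ
below the threshold (Dice 0.98).  `α`, the element radius, the dilation
count and the connectivity are all configurable.

**Bias-field correction.** The measured signal is `v(x) = u(x) f(x)` with a
smooth multiplicative field `f`; additive noise is neglected and the log
transform makes the model additive.  In the log-intensity histogram the
field acts as a Gaussian blurring kernel `F` (FWHM 0.15 log units), so the
measured density is `V = F * U`.  Each iteration sharpens `V` by Wiener
deconvolution, `Û = conj(F̂)/(|F̂|² + Z)·V̂` with noise floor `Z = 0.01`,
maps every voxel to the posterior mean `E[u|v]`, and smooths the residual
`log v − E[u|v]` spatially (masked Gaussian smoothing, FWHM 50 mm) to get
the field increment.  The field is renormalized to zero log-mean (so mean
intensity is preserved to < 1%) and iteration stops when the relative
change of the field's coefficient of variation falls below `1e-3`, or at 50
iterations.  Numerical details that matter:

- the deconvolution FFT is zero-padded to twice the bin count (linear, not
  circular, convolution) and the histogram range is padded past the
  kernel's support — without both, edge ringing is asymmetric at the WM
  end of the histogram and the field estimate drifts several percent even
  on bias-free input;
- the spatial smoothing is a normalized convolution (`smooth(r·m)/smooth(m)`),
  which extrapolates the field smoothly outside the mask;
- the pipeline runs this stage **inside the brain mask**: skull/scalp
  texture pollutes the log-histogram, and extraction-before-bias matches
  the standard preprocessing order for T1 pipelines.  On the default
  phantom (20% bias, 3% noise) the estimated field correlates ≥ 0.94 with
  the true field and every tissue's coefficient of variation decreases.

**Three-Gaussian histogram model.** The brain histogram is modeled as
`p'(i; v) = Σ_k p_k exp(−½((i−μ_k)/σ_k)²)`, `k = 1..3`, where `p_k` is an
amplitude in count units (deliberately no `1/(σ√2π)` factor).  The optimal
`v* = argmin Σ_i [p(i) − p'(i; v)]²` over the `W` gray levels is found by
Levenberg–Marquardt (scipy's `least_squares(method="lm")`) with an analytic
Jacobian, on transformed parameters: `p_k = e^a` keeps amplitudes positive,
logistic transforms keep `μ_k` within per-component bounds and `σ_k` in
`[0.5, W/2]`.  The per-component mean bounds anchor C1 below the GM peak
and C2/C3 above the CSF/GM locations; without them, a histogram with fewer
than three visible modes (the usual case after the Otsu split) lets the
superfluous CSF component migrate onto the GM peak and every class shifts
down one slot.  Initialization comes from the KDE-smoothed histogram
(Gaussian kernel, bandwidth 2): means at the located peaks, amplitudes at
the smoothed heights, widths at each mode's half-FWHM.

Voxels get the class of largest likelihood (ties to the lower class);
voxels brighter than `μ₃ + 3σ₃` become `other` (C4 — bright non-brain
remnants).  In-mask voxels at exactly gray level 0 were removed by the
Otsu split and sit below every modeled component; they are assigned CSF
directly (the C1 "background, noise and CSF" reading).  Confidence is the
top-1/top-2 likelihood ratio; the **ambiguous set** — the refinement's
target — is `{confidence < ρ}` (default ρ = 1.5) plus every voxel with a
differently-labeled 18-connected in-mask neighbor.

**Texture features.** The quantized volume (equal-width, 16 levels over
the in-mask range) yields, per voxel of interest, symmetrized 3-D
co-occurrence matrices over a 21×21×21 window for the 13 canonical
26-neighborhood directions and distances 1–5; 13 classical second-order
statistics per matrix, and per distance the mean and SD of each statistic
across the 13 directions — 26 per distance, 130 per VOI, in the documented
order `(d-1)*26 + stat*2 + {mean, sd}`.  Logs are base 2 with `0·log0 = 0`;
edge windows are clipped, never padded, and flagged.  Both endpoints of a
pair must lie inside the window and be unmasked; the batched counter (a
compiled window loop) is tested for exact equality against a triple-loop
definition.  Degenerate marginals zero the affected information-measure
features, flagged.

**Feature selection.** Classical stepwise discriminant analysis on the
standardized training table: Wilks' Λ = det(W)/det(T) on the candidate
subset, forward entry at partial F ≥ 3.84, backward removal below 2.71,
at most 30 features, ties to the lowest column index (fully deterministic).
Scatter being bilinear, subset Λ values are submatrix determinant ratios
of the one full-table scatter pair.  The standardization parameters are
stored and re-applied at prediction time.

**SVM refinement.** One-vs-rest soft-margin SVMs (C = 100) with a Gaussian
RBF kernel (γ = 1/n_features on standardized, SDA-reduced rows; a
Laplacian RBF is available), trained on 10 000 voxels per image and applied
iteratively: predict the current ambiguous frontier, relabel, grow the
frontier to ambiguous 18-neighbors of changed voxels, stop when stable or
after 10 passes.  Confident voxels are structurally frozen.  Training
labels come from the histogram stage's confident voxels by default
(self-training); in benchmark mode (`svm_train_on_truth`) the 10 000
samples are drawn stratified from the whole brain mask with ground-truth
labels — the protocol appropriate when labeled training images exist,
and the one the paired phantom comparisons use.

**Evaluation.** The kappa index `|S1∩S2| / (|S1∪S2| − ½(|S1\S2|+|S2\S1|))`
simplifies algebraically to Dice `2|∩|/(|S1|+|S2|)` (the denominator is
`(|S1|+|S2|)/2`); Jaccard is `|∩|/|∪|`; `kappa = 2j/(1+j)`.  Both-empty
sets score 1 (configurable to NaN).  Reports are per-tissue one-vs-rest
plus a full palette confusion matrix.

## The phantom: what it emulates and what it does not

The generator produces a nested-ellipsoid head: WM core, GM shell, a
deliberately thick CSF shell (~17% of the half-extent), an air gap, and a
skull-like shell connected to the brain only through three 2-voxel-wide
bridges — the geometry the morphological extraction is designed for (the
default 3×r3 dilation schedule lands on the brain surface of the default
96³ grid).  Intensities: background 0, CSF 50, GM 110, WM 160, skull 120
(between GM and WM, so the distractor survives the mask threshold and must
be removed morphologically).  Within-tissue texture is per-class correlated
noise (Gaussian white noise smoothed at σ = 1.5 voxels) with SDs
(3, 4, 5, 10) for CSF/GM/WM/skull — small relative to the class gaps, as in
T1 tissue.  Degradations follow the simulated-MRI conventions: Rician noise
`sqrt((v+n₁)² + n₂²)` with σ = noise%/100 × the WM mean, and a
multiplicative bias field (random degree-≤2 polynomial, range-normalized so
20% means exactly [0.90, 1.10]) applied before the noise.  Defaults:
96³ grid, 3% noise, 20% bias.

Not emulated: cortical folding, partial-volume mixing at interfaces (every
voxel is purely one tissue), and pulse-sequence physics.  Consequently the
phantom is *easier* than real data for the intensity model (interfaces are
sharp, classes well separated) and *harder* for the texture stage at very
low noise (piecewise-constant windows quantize to degenerate feature
vectors).  Passing the phantom suite shows the chain is implemented
correctly and behaves sensibly under noise and bias; it does not certify
accuracy on real scans.

## Problem sizes used by the test suite

Chosen so the whole suite runs comfortably on one desktop CPU core:
the end-to-end accuracy check runs once at the full default scale (96³,
noise 5%, bias 20%, all stage defaults); the paired
refined-vs-histogram-only comparison runs on 64³ phantoms at noise 7% over
5 seeds with window 11, distances {1,2,3}, 4 000 training samples; the
noise-trend protocol runs on 56³ phantoms over 3 paired seeds with window
9, distances {1,2}, 3 000 samples.  At reduced grid scale the extraction
uses 2 dilations (the 3×r3 default is calibrated to the 96³ CSF-shell
thickness).  Bias-field recovery and skull-stripping are checked at the
full 96³ default.

## Known limitations

- **Refinement on very clean data.**  The SVM's features are window-scale
  aggregates; on a noise-free phantom the quantized windows on either side
  of a curved interface can be feature-identical, so refined boundaries
  carry a small fixed placement error (~0.1 Dice points) that the
  histogram stage does not have.  The refinement therefore pays off from
  roughly 3% noise upward (large, consistent gains at 5–9%) and very
  slightly degrades below that, which also makes the accuracy-vs-noise
  curve non-monotone between 1% and 3% on the phantom.
- **Self-training at boundaries.**  With pseudo-labels, the confident
  training set excludes the boundary shell, so the SVM extrapolates there
  and boundary relabeling is worse than in benchmark (truth-trained) mode.
  Self-training remains the default because it needs no labels; use
  `svm_train_on_truth` whenever labeled training volumes exist.
- The symmetric-Gaussian intensity model has no partial-volume or spatial
  regularization term; heavy field inhomogeneity beyond the smooth
  low-order family, multi-channel input, and DICOM are out of scope.
- The kappa/Jaccard conventions (both-empty = 1; ties at the Otsu
  threshold to background; GLCM edge clipping) are choices a comparison
  against other implementations must replicate.
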