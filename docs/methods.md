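# Methods

This note documents the models, parameter choices and numerical conventions
behind `deltamarch`, and what the synthetic study conditions do and do not
establish about real histology.

## Synthetic tissue model

Patches are composed in optical-density (HED) space and converted to RGB with
the standard published H&E stain vectors (`skimage.color.hed2rgb`), so the
hematoxylin channel recovered by deconvolution equals the planted densities up
to float error. Stain densities: background H 0.05 / E 0.12, nuclei H 0.55 /
E 0.08, vessels E 0.45, nucleolus bumps +0.60 H (Gaussian, σ = 1 px). These
values were chosen once so that (a) nuclei are hematoxylin-dominant, (b) a
smoothed, min-max-normalized hematoxylin bump clears the 0.08 prominence
threshold with ~3× margin, and (c) two bumps ≥ 4.2 px apart remain separate
h-maxima after σ = 1 smoothing.

Grade `g ∈ [1, 4]` drives morphology through piecewise-linear anchors at the
integer grades:

| quantity | g=1 | g=2 | g=3 | g=4 | direction |
|---|---|---|---|---|---|
| tumor nucleus radius (px, 96 px patch) | 3.5 | 4.5 | 5.5 | 7.0 | strictly ↑ |
| expected nucleoli per tumor nucleus | 1.0 | 1.7 | 2.5 | 3.5 | ↑ |
| vasculature area fraction | 0.10 | 0.08 | 0.06 | 0.04 | ↓ |
| non-tumor nucleus radius (px) | 3.0 | 3.0 | 3.0 | 3.0 | flat |

A patch-level `size_factor` (lognormal, log-sd 0.18, clipped to [0.75, 1.35])
multiplies all nuclear radii and models patient-to-patient heterogeneity — the
quantity trajectory pairing is designed to cancel.

**Stochastic state.** The render seed fixes nucleus positions (sequential
rejection sampling with a grade-independent exclusion radius, with up to six
seed-derived restart rounds near packing capacity), ellipse eccentricities
(≤ 1.07, keeping pixel area within ~15 % of πr²), per-nucleus radius jitter,
nucleolus placement, and the vessel ribbon. All seeded draws are independent
of the continuous parameters, so decoding different semantic codes with the
same state moves *sizes*, not *positions*. Nucleolus counts are Poisson
quantiles at per-nucleus seeded uniforms — monotone in the rate, so raising
grade with the seed fixed can only add nucleoli. The vessel ribbon is
generated once per seed out to a 0.12 area fraction; a patch's density selects
a prefix, so lower density removes the tail of the *same* vessel rather than
redrawing.

**Analytic backend.** The semantic code is `(grade, n_tumor, n_other,
log size_factor)`; the state is the seed; decode re-renders. Encode/decode
round-trips are bit-exact and the true grade direction is the first coordinate
axis, which gives oracle tests for the latent classifier (cosine with the
recovered grade-4 weight vector > 0.9) and for traversal monotonicity.
Out-of-range codes are clipped with a recorded warning.

## Latent model and traversal

The grade model is a multinomial logistic regression on per-dimension
standardized codes (statistics frozen from the training cohort). Traversal
shifts the standardized code by `step_scale · √d · w_t/‖w_t‖` per step
(`step_scale` = 1, `d` = code length), decoding with the fixed state after
each shift, halting at the predicted target grade or after 4 steps; 20
strictly interior nodes are then interpolated linearly in standardized space.
The target-class logit is exactly linear along the path, so its strict
increase across nodes is asserted, not sampled. Grade prediction from images
uses stain-space features (component areas, nuclear and vessel-colored area
fractions, component density) under a multinomial logistic model; on default
synthetic cohorts its held-out accuracy is effectively 1.0, and ≥ 80 % of
grade-1→4 traversals terminate with a confirmed grade-4 image.

Within-grade control swaps decode patch B's semantic code with patch A's
state; a self-swap is the identity reconstruction, while distinct same-slide
pairs are rejected ("different patient" contract).

## Delta-Maps and enrichment

Pipeline order is fixed: per-channel feature subtraction → bilinear upscaling
(half-pixel convention, align-corners off) of each channel to image size →
absolute value → channel mean. "Normalization by the per-patch minimum" is
read as min-max scaling to [0, 1] (min-subtraction alone would make the 0.5
binarization threshold unit-dependent); a `mode="min"` flag provides the
alternative reading. Binarization is strictly greater-than. A constant raw
map normalizes to all zeros. The default filter is a seeded, fixed
convolutional stack (3→16→32 channels, ReLU + average pooling); differencing
random projections of local content localizes change without training, and
the toy autoencoder's encoder can substitute via the same interface.
Sub-transition boundaries are the first node whose predicted grade reaches
each intermediate grade.

Ghost-nucleus removal keeps a merged component only if it overlaps ≥ 1
nucleus pixel in both endpoint masks (weakest sufficient criterion).
Vessel/nucleus conflict pixels are reassigned by a fair seeded coin. Jaccard
ratios with a zero baseline are recorded as +∞ and kept in medians (a warning
fires if they exceed 5 % of rows). The enrichment t-test is one-sided and
paired (per-patch true vs random), with an unpaired flag for sensitivity.

## Power analysis

The sign test drops ties and uses the exact upper binomial tail. Unpaired
strategies pair values by draw index after independent draws; sampling within
a repetition is without replacement. The mean of natural-log p over 1,000
repetitions summarizes power; with N = 100 pairs the floor is
ln 2⁻¹⁰⁰ ≈ −69.3.

Synthetic per-grade samples are taken from trajectory nodes by *progression*
(the node whose code grade is nearest the target; for non-analytic backends,
the linear position along the path), not by the image predictor's label.
Selecting nodes by predicted grade conditions the sampled phenotype on an
area-driven classifier and collapses within-grade heterogeneity — both paired
and unpaired comparisons then sit at the p-floor and the pairing question
becomes vacuous. Progression sampling preserves the heterogeneity that
pairing is supposed to cancel; per-node predictions are still computed and
reported. The pairing advantage is asserted for adjacent grade pairs; for the
1→4 comparison the area effect is so large relative to heterogeneity that
every strategy saturates, consistent with pairing gains concentrating where
class differences are subtle.

## Study conditions and scale

Default study sizes (chosen as desk-scale conditions): cohorts of 100 patches
per grade at 96 px for phenotype recovery; 200 trajectories for enrichment
recovery, generated under anchors that hold nucleoli rate and vessel density
constant so that tumor nuclei are the sole grade-linked change; 140
trajectories for the power study; the determinism check runs a reduced
end-to-end configuration (16 patches/grade, 14 trajectories) twice, since
byte-level reproducibility does not depend on size. The toy autoencoder
trains on 160 patches at 32 px for 40 epochs (~30 s CPU); held-out SSIM
plateaus near 0.45–0.47 at this scale, and its test threshold (0.40) was set
from that pilot. A single experiment seed fans out to per-stage seeds through
`numpy` `SeedSequence` spawning.

## What the synthetic study does not show

The generator emulates grade-linked morphology, not histology: no texture,
staining variability, sectioning artifacts, overlapping or clustered nuclei,
sarcomatoid/rhabdoid grade-4 patterns, or imperfect segmentation (masks are
exact by construction). Passing tests therefore establish that the pipeline
*recovers planted causal structure* — they do not certify performance on real
whole-slide cohorts, where segmentation error, stain variation and weaker
effect sizes all enter. The analytic backend's exactness removes
generative-model artifacts; ghost-nucleus handling is consequently exercised
mainly by construction rather than by naturally occurring artifacts.

## Known limitations

- The toy autoencoder's codes separate grade only weakly at desk scale;
  quantitative claims use the analytic backend.
- Nucleolus capacity in small (grade-1) nuclei is geometrically limited, so
  corrected counts at grade 1 are near zero; monotonicity across grades is
  preserved.
- The vessel prefix construction makes lower-grade vessel masks supersets of
  higher-grade ones within a trajectory; convenient and measurable, but not a
  biological claim about vessel regression geometry.
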