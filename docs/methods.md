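# Methods

This note documents the models and numerical choices behind `visattn`, in
the spirit of a statistical-software methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic
validation does and does not establish.

## Gaze heat maps

A fixation is a (x, y, onset, duration) event; input is assumed already
fixation-segmented (as in a Tobii tabular export) — raw-gaze event
detection is out of scope. Coordinates are 0-based raster coordinates
(origin top-left, x = column). Fixations landing outside the image are
clipped to the boundary rather than dropped: partially off-screen gaze
still carries signal, and the clipped count is logged.

`fixations_to_map` deposits each fixation's duration under a radial kernel
of support `radius_px` (default **25 px**, the export radius the downstream
comparisons assume; coarser radii blur the comparisons). The kernel shape
is a configurable choice — commercial eye-tracking software does not
document its default precisely — with linear falloff (1 − r/R, clipped at
0) as default and Gaussian (sd = R/2, truncated at R) and flat-disc
variants available. Kernels are normalized to unit sum so that a map's
total mass equals summed fixation duration in ms; the operation is linear
in duration and additive over fixations.

Per-participant maps are normalized to unit mass before group averaging so
that participants with longer total fixation time do not dominate the group
average. Smoothing is a box filter (default **11 px**, odd) with
truncated-edge handling: each output cell is the mean over the in-bounds
part of the window, so constant maps are exactly preserved. 11 px is a
display-scale choice (≈ 2.5% of a 448-px image) that suppresses
pixel-level sampling noise without moving residual peaks; results reported
here are insensitive to moderate changes.

## Common-attention subtraction

Face viewing is dominated by a generic eyes/nose/mouth pattern common to
all stimuli. Each group's *common attention* is the normalized mean of its
per-stimulus average maps over all stimuli; it is estimated and subtracted
**separately per group** (clinician maps are never corrected with the
non-clinician pattern — this is enforced). Subtraction acts on per-stimulus
group averages by default; a per-participant variant is available by
passing a precomputed common pattern. Negative residuals (less-than-typical
attention) are clipped to 0: the analysis targets surplus attention, and
the residual is deliberately not renormalized because its absolute
magnitude is meaningful. The degenerate single-participant, single-stimulus
case correctly yields an all-zero residual (the common pattern is the map
itself).

## Thresholded IoU comparison

Binarization thresholds are quantiles of a map's **nonzero** values:
low = 0.25-quantile (strips spurious weak signal), high = 0.75-quantile
(keeps only the strongest attention). Quantiles over nonzero cells only,
because most of a face stimulus is zero-attention background and including
it would drive every threshold to zero. Cells strictly above the threshold
enter the mask, so the high mask is always a subset of the low mask, and
raising the quantile can never grow the mask. Masks from different
threshold kinds cannot be compared (enforced); the IoU of two empty masks
is defined as 0 with a warning, so pooled analyses stay finite.

Bootstrap uncertainty resamples **participants** with replacement,
independently within each group — the participant is the exchangeable
unit; pixels are strongly spatially dependent and resampling them would
fake precision. Each replicate recomputes the full statistic
(average → subtract common → smooth → binarize → IoU); the standard error
is the replicate standard deviation (ddof = 1). Default 1000 replicates for
final analyses; the packaged end-to-end runs use 200 (pooled effects move
by < 0.01 beyond that; the per-stimulus se is the only quantity that
benefits from more).

## Random-effects pooling

Per-stimulus IoU effects are pooled with the DerSimonian–Laird
moment estimator (the standard "RE Model" of forest-plot software);
the implementation follows the closed form given in the README and is
verified in tests against statsmodels' independent implementation to 1e-8.
Zero standard errors (degenerate single-member subgroups) are floored at
1e-6 with a warning so weights stay finite. When the heterogeneity estimate
τ² is 0, the pooled effect reduces exactly to fixed-effect
inverse-variance pooling. Raw IoU is pooled; a logit transform was
considered and rejected as the default because per-stimulus IoUs here sit
well inside (0, 1) and the raw scale is the one readers of a forest plot
expect.

Known limitation: the 1.96-normal CI ignores the sampling noise of τ̂².
With k = 16 stimuli this makes the interval slightly anticonservative — in
the packaged coverage simulation (true mean 0.45, between-stimulus sd 0.05,
known per-stimulus se drawn uniformly from 0.03–0.08, seeds 0–99) the 95%
CI covers the true mean in 92/100 replications rather than ≥ 95. This is
the documented finite-k behavior of DerSimonian–Laird, not an
implementation artifact; a Knapp–Hartung-type t-adjustment would widen the
interval but is not part of the prescribed estimator.

## Occlusion saliency

For every box position on the stride grid (default box **20 px**, stride
**10 px**, so each interior pixel is covered by exactly 4 boxes — asserted
via an explicit coverage-count map), the occluded image is re-classified
and the drop p₀ − p(occluded) of the target label recorded. A pixel's
saliency is the mean drop over its covering boxes (footprint attribution;
center attribution is a config option), clipped at 0 — occlusion that
*helps* the target class is not "importance" in this rendering convention.
The occluder fill is the per-channel image mean by default (least
distribution shift); mid-gray and zero fills are options. With
stride = box the map provably equals the naive one-box-at-a-time
measurement, which the tests check exactly. Saliency maps are
nearest-neighbor resampled to the gaze map's grid before IoU so mask
topology is preserved, and both sides are binarized at the *same* quantile
kind.

Training a deep classifier is out of scope; `ClassifierAdapter` accepts any
callable satisfying the probability contract (nonnegative, sums to 1 within
1e-6, checked on every call), with a default 448-px input convention.

## Cohort statistics

Judgment accuracy is analyzed per response: a 2×2 group × correct/incorrect
table, per-group percent correct, and an **uncorrected** Pearson chi-square
with df = 1. No Yates continuity correction is applied — at these margins
(~350 responses per group) the correction is unnecessary and changes the
p-value materially; the uncorrected statistic is the documented choice.
Missing judgments are dropped from the counts (and logged): discarded
eye-tracking results leave participant × stimulus holes that the whole
pipeline tolerates.

AOI metrics use a boundary-inclusive, even-odd point-in-polygon rule on
the fixation *center* ("whole fixation" = center inside; a stricter
whole-dispersion rule would need fixation extents, which tabular exports
do not carry). Duration-of-fixation sums inside-fixation durations;
time-to-first-whole-fixation is the onset of the earliest inside-fixation,
absent if the AOI was never fixated.

Participant subgroups ("successful" / "underperforming") are formed **per
stimulus** from the response records: the same participant can be
successful on one image and underperforming on another, and the tests
assert this membership rule explicitly.

## Synthetic study generator

The generator emulates the *structure* of a two-group face-inspection
experiment: 22 clinicians + 22 non-clinicians, 16 stimuli (10 affected, 6
unaffected), 448-px images, 7 s viewing per trial, and target judgment
accuracies of 85.6% / 76.9%. Gaze is a Gaussian mixture: three common
components at fixed eye/nose/mouth positions (weights 0.45/0.30/0.25, sds
9/6/6% of the image side) shared by every stimulus, plus one planted
stimulus-specific component (sd 5%) at a random location kept clear of
borders and of the common centers — the "dysmorphic feature". Clinicians
give it mixture weight 0.35 vs 0.12 for non-clinicians (clinicians attend
diagnostic features more; non-clinicians mostly show generic face-viewing).
A `disjoint_specific` mode plants *separate* feature locations per group to
create maximally different group attention. Fixation counts are
Poisson(18) per 7-s trial; durations are Gamma(shape 2, mean 300 ms) — a
typical fixation-duration scale — with 30–90 ms saccade gaps, rescaled if
a sampled trial would overrun the viewing window. Stimulus images are
smooth random fields with brightened component regions; no faces are
synthesized or required. All generators are pure functions of
(config, seed).

The toy classifier scores the true label as a logistic function of the mean
pixel intensity inside the stimulus's planted-feature box, spreading the
remaining mass evenly over other labels. Its occlusion saliency is
therefore analytically confined to that box, giving a ground-truth target
for the saliency tests.

**What passing tests show — and don't.** On this generator the pipeline
(i) recovers planted feature locations from residual maps (16/16 stimuli at
the default scale in the packaged runs, ≥ 14/16 asserted), (ii) reproduces
the qualitative threshold effect — groups with disjoint strong attention
look similar at the low threshold and diverge at the high one — and
(iii) yields saliency-vs-human IoUs far below human-vs-human ones. Real
gaze has saccade dynamics, center bias, temporal order effects,
inter-individual scan-path styles, and stimulus-dependent feature salience
that a static Gaussian mixture does not model; passing here validates the
*computational pipeline*, not claims about human vision. Absolute IoU
values on synthetic data depend on generator settings and should not be
read as predictions for any real cohort.

## Problem sizes and determinism

The packaged end-to-end runs use the default study scale (44 participants ×
16 stimuli × 448-px maps) with 200 bootstrap replicates per stimulus
comparison; the directional-threshold experiment uses 60 replicates per
stimulus over 5 cohort seeds, and the calibration experiment 200 replicated
response sets. Every stochastic step takes an explicit seed or Generator;
per-participant and per-stimulus substreams are derived via CRC-keyed
`numpy` seed sequences, so any slice of a study can be regenerated
independently and runs are reproducible bit-for-bit.
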