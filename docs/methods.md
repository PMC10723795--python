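# Methods

This note documents the models and procedures implemented in `nucleoscore`,
the parameters that matter, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## The nucleolar normality score

The nucleolus is organized around the fibrillar center (FC; rDNA with bound
UBF and RNA Pol I) and the granular component (GC; nucleolin, NPM1). Under
nucleolar stress the two markers move in opposite directions: GC proteins
disperse into the nucleoplasm, while FC proteins condense (peripheral
"stress caps" under Pol I inhibition, extended strings under transcriptional
CDK inhibition). A single per-cell ratio captures both movements. With
integrated (summed) intensities over masks,

    I_nucleoplasm(c) = I_nucleus(c) − I_nucleolar(c)        for each channel c

    score = [I_nucleolar(GC) / I_nucleoplasm(GC)] / [I_nucleolar(FC) / I_nucleoplasm(FC)]

The score is dimensionless, invariant to any per-channel positive gain
(exposure, antibody brightness), and decreases monotonically as GC signal
moves out of the nucleolus or FC signal condenses into it. Cells with no
detected nucleoli or a non-positive denominator carry an undefined score;
they are excluded from well means and tallied in QC columns rather than
imputed, because injecting zeros would bias well averages by cell-density
artifacts. Integrated, not mean, intensities are used throughout, so the
score also responds to compartment area changes.

## Segmentation

Nuclei: rolling-ball background subtraction of the DNA counterstain
(default radius 50 px, "large"), global threshold at 10% of the
background-subtracted image maximum, hole filling, removal of
border-touching objects, and an inclusive area gate (default
1,000–30,000 px²). An image that is constant after subtraction yields an
explicit empty mask.

Nucleoli: rolling-ball subtraction of the FC-marker channel with a radius
chosen large relative to the nucleus so diffuse nucleoplasmic signal
survives, Gaussian smoothing at sigma 0.7 px, then an independent
per-nucleus threshold at 40% of that nucleus's (max − min) span of the
smoothed image, clipped to the nucleus; objects smaller than 4 px are
discarded. The per-nucleus min–max threshold makes segmentation exactly
invariant to positive scaling of the marker channel and independent across
nuclei. Pixels equal to the threshold are foreground — min–max thresholds
frequently hit exact pixel values on synthetic images, so the tie-break is
part of the contract. Hole filling is applied to nuclei only: nucleoli
legitimately exclude FC-negative interior in dissolution phenotypes.

Numerical choices:

* Intensities are always measured on the background-subtracted but
  **unblurred** channel; smoothing exists only to define masks, and
  measuring on blurred data would leak intensity across the
  nucleolus/nucleoplasm boundary.
* The nucleus threshold is taken from the background-subtracted image's
  maximum (whether the original plugin used the raw maximum is not
  knowable from its description; this choice is recorded in run metadata).
* Rolling-ball radii above 32 px are computed on a block-minimum-downscaled
  image (shrink factor ~radius/16) with a proportionally smaller ball, then
  enlarged by interpolation and clipped from above by the image. The block
  minimum (rather than a mean) prevents bright objects from smearing into
  the background estimate; the clip preserves the defining property
  0 ≤ output ≤ input.
* Connectivity defaults to 8-connected for both mask types.
* All arrays are promoted to float64 before arithmetic so unsigned camera
  data cannot wrap under subtraction.

## Screen aggregation and hit calling

Per-cell scores are averaged per field, then field means per well
(two-stage averaging, so dense fields do not dominate a well); fields with
zero scored cells are dropped from the well mean and counted. Well scores
and cell counts are normalized to the vehicle (DMSO) mean. Vehicle
statistics (sample mean and SD, n−1) pool all vehicle wells by default,
with per-plate pooling available. A compound is a hit at a concentration
when its well score falls below mean − k·SD with k = 2; the rule is
one-sided because nucleolar stress only lowers the score (a two-sided mode
exists). Hit calling is invariant under common affine rescaling of scores
and vehicle statistics, so it is indifferent to whether raw or
vehicle-normalized scores are used. Hits are categorized by the
concentration set at which they fire: both, 10 µM only, 1 µM only, none.

Target-class enrichment among hits uses the hypergeometric upper tail
(one-sided Fisher): with M library compounds, K in a class, n hits and k
class hits, p = P(X ≥ k), and fold enrichment (k/n)/(K/M). Raw p-values
are reported with a 0.05 significance flag; no multiple-testing correction
is applied by default (a Benjamini–Hochberg flag exists) because the
screen's convention is raw significance tiers.

## FRAP

Raw traces carry the bleached-ROI mean, an extracellular background ROI,
and the whole-nucleus mean. Double normalization

    F_norm = [(F_roi − F_bg)/(F_whole − F_bg)] · [(F_whole − F_bg)_pre/(F_roi − F_bg)_pre]

sets the pre-bleach level to 1 and cancels acquisition photobleaching
exactly, because frame-wise attenuation multiplies ROI and whole-nucleus
signal alike. The post-bleach curve is fit with the bounded two-component
recovery

    F(t′) = F0 + A1(1 − e^(−k1 t′)) + A2(1 − e^(−k2 t′)),  A ≥ 0, k1 ≥ k2 > 0.

Initialization is deterministic and seed-free: F0 from the first
post-bleach point, the plateau from the mean of the final 10% of points,
and rate seeds from a coarse log-spaced grid (10 points over 10⁻³–10^1.5
s⁻¹, all ordered pairs); the best least-squares solution is kept and the
convergence flag is honest. T½ is defined on the composite fitted curve —
the time to reach halfway from F0 to the plateau — found by bracketing and
Brent root finding (analytically ln 2/k for a single component). Because
two-exponential fits are degenerate when rates are close, fits with
k1/k2 < 1.5 are re-run as single-component and flagged. Group summaries
report mean ± SD of T½ over converged fits and Welch (unequal-variance)
two-sample t-tests against a reference group.

## Phosphosite filtering

Protein abundance classification: enriched iff LogFC > 1.5 and FDR < 0.05,
depleted iff LogFC < −1.5 and FDR < 0.05, else unchanged. Phosphosite
spectral-count ratios are untreated/treated totals with 0 → 0.1
replacement applied to either side (symmetric, so reciprocal pairs
multiply to 1 when both counts are positive); a site with zero spectra on
both sides carries no evidence and is dropped with a notice. Sites are
excluded when any single untreated replicate has fewer than two spectra
(the stricter per-replicate reading; a summed-total mode exists) or when
the parent protein shows a significant abundance *decrease* (FDR < 10⁻⁴
with negative LogFC) under any analyzed drug — a decreased protein would
trivially produce decreased phosphopeptide counts. The "decreased in
both treatments" subset is ratio > 1 under every drug.

## Synthetic data

The generator renders the four stress phenotypes as disk-based geometry:
nuclei are uniform disks (default radius 22 ± 2 px, five per 256 × 256
field), each holding 1–4 nucleolar structures. Per-nucleus intensity pools
(arbitrary units): GC total 2·10⁵ of which a phenotype-specific fraction f
is nucleoplasmic; structural FC 10⁵; diffuse nucleoplasmic FC 2·10⁴; DNA
amplitude 150/px. Defaults per phenotype: normal f = 0.05 with 5-px
nucleolar disks; metabolic f = 0.15 with shrunken 3-px disks;
canonical stress f = 0.50 with 4-px remnants bearing paired peripheral
caps and 40% of the diffuse FC pool relocated into the caps (raising the
FC ratio, as cap intensities rise while the score falls); dissolution
f = 0.95 with the FC pool spread along random-walk strings ~2–3 px wide.
These settings give analytic scores of about 3.8 / 1.13 / 0.11 / 0.011,
an ordering (normal > metabolic > canonical > dissolution) that the
pipeline reproduces on noisy renders with non-overlapping confidence
intervals.

Noise is Poisson on the noiseless signal plus additive Gaussian read noise
(sigma 2), the standard camera model; identical parameters and seed give
bit-identical fields. Ground truth is bookkept by summing the noiseless
arrays over the generator's own masks, so compartment conservation is
exact by construction and the analytic score is directly comparable to
pipeline output. The GC marker is co-localized with the FC structures
rather than forming a surrounding shell, nuclei are non-overlapping
sharp-edged disks, and there is no point-spread function, illumination
gradient, or 3D structure — so passing tests demonstrate the correctness
of the measurement and decision logic, not robustness to real-microscope
artifacts such as touching nuclei, uneven illumination, or focus drift.

Plate simulation: each compound is assayed at 1 and 10 µM; well-level
means are Normal(1, 0.05²) for vehicle and null compounds; planted hits
are shifted down by a configurable multiple of the vehicle SD (default 6)
at 10 µM, and also at 1 µM for "both"-category hits; per-cell scores add
Normal(0, 0.1²) noise split across 4 fields. Library-scale defaults mirror
the screened collection: 1180 compounds, 83 planted both-concentration
hits, 69 ten-µM-only hits. The null calibration of the k = 2 rule is run
at the well level (one cell per well, zero cell noise) against the true
generating parameters, which isolates the rule itself from vehicle-set
estimation error; estimated-vehicle behavior is tested separately.

FRAP simulation: raw ROI/background/whole-nucleus series are
forward-simulated from the normalized model (default parameters solved to
give a composite T½ of 4.6 s, the scale of GC-marker recovery in
unstressed cells, with rate ratio 8), optional per-frame acquisition
bleaching applied to ROI and whole-nucleus signal alike, and Gaussian
noise on the ROI. The whole-nucleus signal is held constant across the
bleach pulse (small-ROI approximation), which makes the double
normalization recover the model curve to machine precision in the
noiseless case.

## Problem sizes

Default verification sizes, chosen to give stable statistics at desk
scale: 20 fields per phenotype (≈100 nuclei each for segmentation
accuracy and phenotype discrimination), 10,000 null compounds for rule
calibration, 300 random enrichment instances with library ≤ 25 against
exact combinatorial enumeration, and 200 noisy FRAP traces (sigma 0.02)
for half-time recovery.

## Known limitations

* Touching nuclei are not split (no watershed); the generator places
  non-overlapping nuclei, and crowded real fields would need a separation
  step upstream.
* The rolling-ball downscale approximation can underestimate background
  curvature at scales near the shrink factor; radii ≤ 32 px are exact.
* Two-exponential FRAP fits with rate ratios below ~1.5 are reported as
  single-component by design; true two-component dynamics in that regime
  are not recoverable from single-curve data.
* The enrichment test treats the library as the sampling frame; it does
  not model correlated hits (e.g. chemical series of near-identical
  compounds).
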