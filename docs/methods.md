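# Methods

This note documents the models, conventions and design choices behind
`imcpatch`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Patch quantification

IMC produces count-valued rasters (metal-isotope "dual counts") at ~1 μm
pixel pitch with no autofluorescence. Because Shh and TGF-β are secreted,
the unit of analysis is a square tissue tile rather than a segmented cell.

* **Tiling.** Patch side in pixels is `round(patch_size_um / pixel_size_um)`
  (default 50 μm at 1 μm/px). The grid is anchored at the image origin
  (row-major, 0-based, half-open intervals) and incomplete edge tiles are
  dropped, so every patch covers the same area and patch means are directly
  comparable; the patch count is `floor(rows/p)·floor(cols/p)`. The patch
  statistic is the arithmetic mean of pixel intensities — invariant to small
  tile-size differences, unlike a sum.
* **Pixel size.** When image metadata carries none, cohort readers default
  to 1.0 μm/px, the standard ablation pitch of Hyperion-class instruments;
  it is overridable per cohort.
* **Scaling.** For each sample and marker, the reference is the 99th
  percentile of that sample's patch means, computed with numpy's linear
  interpolation between order statistics (the convention is fixed and
  asserted by tests; any fixed convention would do). Scaled value =
  raw mean / reference. Per-sample scope corrects staining/acquisition
  intensity differences between samples so one cohort-wide split threshold
  is meaningful; a pooled-cohort mode (`pooled_scaling`) exists for
  sensitivity analysis. A zero reference maps that (sample, marker) to 0
  with a warning rather than dividing by zero.
* **Outliers.** A patch whose scaled value exceeds 1.0 in any analysis
  marker exceeded its own sample's 99th-percentile reference and is flagged;
  the boundary (exactly 1.0) is kept. By construction ≈1% of patches per
  marker are flagged, ≈3% overall for three independent channels; this is
  where hot-pixel artifacts land. Note the flip side: an artifact class more
  prevalent than ~1% of patches cannot be removed by a 99th-percentile rule.
* **Low signal.** Tissue presence is read from the DNA channel: scaled DNA
  below 0.05 flags a patch. On the synthetic generator below this filter is
  essentially inactive (the simulated DNA background keeps scaled DNA near
  1), so its behavior is exercised on constructed images with genuinely
  blank regions; on real acquisitions it removes empty resin/background
  tiles. QC flags are independent given a scaled table, so the two flagging
  passes commute, and analysis operations see only flag-free records.

## Density split

Pooled scaled TGF-β values are modeled as bimodal: background tissue versus
fibrotic regions. The density is a Gaussian KDE (Scott's-rule bandwidth by
default, configurable) evaluated on a 512-point uniform grid over
[0, max value] and renormalized to unit trapezoid integral (truncation at 0
clips kernel tails). The split threshold is the deepest interior strict
local minimum inside the search range (0.05, 0.95) — the range excludes KDE
boundary artifacts — with ties broken toward the smaller value. If no
interior minimum exists (unimodal or degenerate data) the pipeline falls
back to the fixed threshold 0.2, the published split point for this
analysis, and records `method="fixed_override"`. Patches at or above the
threshold are "high"; the boundary convention is arbitrary but fixed.
Identical curves always produce identical thresholds.

Two behaviors of the deepest-minimum rule are worth knowing. First, on
finite samples a KDE can carry shallow spurious minima in sparse tail
regions; the search range mitigates but does not eliminate this. Second, on
full synthetic image cohorts the background mode is smeared upward by
partially fibrotic patches and between-sample reference variation, so the
detected valley typically lands near 0.4–0.65 rather than at 0.2; the
threshold-recovery guarantees below are therefore stated on explicit bimodal
mixtures, where the true valley is known analytically.

## Group statistics

Scaled Shh is compared between TGF-β-high and TGF-β-low patches with
Student's unpaired two-tailed t-test (pooled variance), the study's stated
procedure; Welch's t and Mann-Whitney are selectable because patch
intensities can be skewed. `difference` is mean(high) − mean(low): positive
means Shh is enriched where TGF-β is high. Strata: each grade present; a
case-vs-control contrast (`MF_vs_control`: scaled Shh among high patches,
G1–G3 vs G0); and the pooled-case high-vs-low contrast (`MF_high_vs_low`),
which is the headline co-localization test. Groups need ≥2 patches each or
the comparison is reported with status `insufficient patches` instead of a
number. No multiple-testing correction is applied by default (none was in
the source analysis); Bonferroni over the per-grade tests is available.

The unit of analysis is the patch, which pseudo-replicates within images; a
per-sample mode (`per_sample=True`: mean per sample and group, then the test
across samples) is provided and off by default to match the published
analysis.

A caveat documented deliberately: per-sample scaling absorbs absolute
between-sample intensity differences, so a between-cohort contrast in scaled
units (MF vs control) is weak by construction whenever a control sample's
Shh is spatially flat — such a sample scales to ≈1 everywhere regardless of
its absolute brightness. The within-sample/within-stratum high-vs-low
contrasts are the quantities this normalization is designed for.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
marrow histology:

* **Fibrosis field.** Smoothed white noise (Gaussian filter, σ = 40 px)
  thresholded at the (1 − f) quantile, giving fibrotic regions with ~100 μm
  spatial scale and an *exact* area fraction f per grade
  (G0 0.02, G1 0.10, G2 0.25, G3 0.40).
* **Channels.** TGF-β ~ Poisson(1 + 8·mask); Shh ~ Poisson(2 + e_g·mask)
  with grade effects e_g = {0, 1, 2, 3}; DNA ~ Poisson(10) inside 3-px
  nucleus disks placed uniformly at 2000 nuclei/mm², Poisson(1) elsewhere.
  Each pixel of each channel is independently replaced by 500 counts with
  probability 10⁻⁴ (hot pixels), exercising the outlier-discard step.
* **Cohort.** 8 images per grade (32 total, matching the emulated cohort
  size), 500×500 px at 1 μm/px; G0 doubles as the control stratum
  (`is_case=False`). Per-image seeds are hashed from (cohort seed, image
  index), so a seed fully determines the cohort bit-for-bit.

What the generator does **not** model: trabecular/adipose structure, channel
spillover, autofluorescence (absent in IMC), spatial correlation of noise
beyond the fibrosis field, or per-patient staining variability beyond
Poisson sampling. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and its statistical behavior under the stated model,
not robustness to every real-acquisition artifact.

For threshold-recovery studies a separate helper draws values from a
two-component truncated-normal mixture (low component N(0.4·m, 0.04), high
component N(m + 0.4, 0.18), both truncated to [0, ∞)) whose low-component
weight is solved analytically so the mixture density is stationary exactly
at the target minimum m; tests verify the valley location by brute-force
grid evaluation of the analytic density. With n = 20000 draws per cohort,
Scott-bandwidth smoothing biases the detected valley upward by roughly
+0.02 at m = 0.2 (kernel convolution widens the narrow background mode);
the recovery tolerance of ±0.05 on the mean over ≥20 cohorts accounts
for this known, bandwidth-driven bias.

## ΔΔCt

Fold change = 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_sample −
mean over control samples of (Ct_target − Ct_ref). Reactions with Ct
strictly above 40 cycles, or reported "undetermined", are negative for
expression; any negative input yields status `not_expressed` and no number.
Replicate Cts are averaged per (sample, condition, gene) before the
arithmetic — Ct is log-scale, so this is a geometric mean of expression —
and an undetermined replicate poisons its group's mean, propagating to a
negative call. Identities guaranteed and tested: fold of a sample against
itself is exactly 1; swapping sample and control inverts the fold; adding a
constant to all four Cts leaves it unchanged. Amplification-efficiency
correction is out of scope (the method assumes perfect doubling).

## Problem sizes and numerics

Simulation-based checks use deliberately chosen sizes: the headline
co-localization check runs the default cohort (32 × 500×500 px, ~3100
QC-passing patches); type-I-error calibration uses 200 null cohorts
(all Shh effects 0) of 4 × 300×300 px with one image per grade — one image
per grade keeps the scaling reference common to both groups within a
stratum, so the null is exact — yielding ~520 computed tests whose
empirical rejection rate at α = 0.05 is required to sit inside the 95%
binomial band; effect-size monotonicity uses 20 cohorts of 8 × 300×300 px.
Floating-point conventions: t statistics match the closed-form
pooled-variance formula to 1e-10; extremely large t underflows the two-sided
p to 0.0, which is reported as computed rather than clamped.

## Known limitations

* The deepest-valley rule has no prominence floor; a prominence-aware
  detector would be more robust to tail wiggles on small samples.
* Patch-level testing overstates precision on real cohorts (within-image
  correlation); use `per_sample=True` for inference robust to
  pseudo-replication.
* The 99th-percentile outlier rule removes at most ~1% of patches per
  marker by construction and cannot absorb higher-prevalence artifacts.
* Proprietary acquisition formats (.mcd/.txt), spillover compensation and
  cell segmentation are out of scope; inputs are multipage/OME TIFF plus
  CSV panel and metadata tables.
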