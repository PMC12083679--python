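# imcpatch

Patch-based co-localization analysis of imaging mass cytometry (IMC) for
bone-marrow fibrosis, with a synthetic cohort generator that makes the whole
pipeline runnable and testable without clinical data.

## The problem

In myelofibrosis, the secreted ligands Sonic hedgehog (Shh) and TGF-β act in
the extracellular space, so the cell-segmentation approach standard in IMC
analysis is a poor fit: the signal of interest lives between cells. This
package instead quantifies markers on a fixed grid of square tissue tiles
("patches") and asks a spatial question — *is Shh enriched where TGF-β is
high, and does that co-localization grow with fibrosis grade (G0–G3)?* It is
aimed at people analyzing multiplexed tissue images of marrow (or any tissue
where the analyte is secreted), and at anyone who needs a reproducible,
fully-simulatable reference implementation of the patch approach.

## The method

For each sample image with channels DNA, Shh and TGF-β (counts per 1 μm
pixel):

1. **Patches.** Tile the image into non-overlapping 50 μm squares; each
   patch's statistic is the mean pixel intensity per channel,
   `x[i,m] = mean of channel m over patch i`.
2. **Scaling.** Per sample and per marker, divide by the 99th percentile of
   the patch means: `s[i,m] = x[i,m] / P99(x[·,m])`. This puts channels and
   acquisitions on a common dimensionless scale.
3. **QC.** Discard outlier patches (`s[i,m] > 1` for any marker — above the
   sample's own reference, where hot-pixel artifacts land) and patches with
   low to no signal (`s[i,DNA] < 0.05`, no tissue).
4. **Split.** Pool the cohort's scaled TGF-β values, estimate their density
   (Gaussian KDE, Scott bandwidth), and split patches into TGF-β-high
   (`s[i,TGFb] ≥ τ`) and TGF-β-low at the deepest interior local minimum τ
   of the density; if no interior valley exists the split falls back to the
   fixed published threshold τ = 0.2.
5. **Statistics.** Compare scaled Shh between high and low patches with
   Student's unpaired two-tailed t-test, per grade and pooled over
   myelofibrosis cases, plus a case-vs-control contrast among high patches.

The generator (`imcpatch.simulate`) produces cohorts with exactly this
structure: a smoothed-noise latent fibrosis field thresholded so the fibrotic
area fraction per grade is exact, Poisson channels with grade-dependent Shh
enrichment inside the fibrotic mask, nucleus disks for DNA, and rare hot
pixels. An auxiliary module computes relative qPCR expression by the ΔΔCt
method (fold = 2^−ΔΔCt, negative when Ct > 40).

## Worked example

`python examples/04_grade_comparison.py` simulates the default 32-image
cohort (8 per grade, 500×500 px) and runs the full pipeline:

```
QC: {'outlier': 89, 'low_signal': 0, 'total_removed': 89}
split threshold: 0.628 (detected_local_minimum), 503 high / 2608 low

stratum          n_high  n_low    diff        t  p
G0                   15    762   0.001     0.05  0.958  [ok]
G1                   56    725   0.239    32.23  1.79e-145  [ok]
G2                  157    619   0.386    58.51  2.24e-286  [ok]
G3                  275    502   0.456    65.53  0  [ok]
MF_vs_control       488     15   0.048     2.64  0.00867  [ok]
MF_high_vs_low      488   1846   0.344    59.17  0  [ok]
```

`diff` is mean scaled Shh in TGF-β-high minus TGF-β-low patches. It is ≈0 in
unfibrotic G0 images (no Shh enrichment was simulated there) and rises
monotonically to 0.456 at grade G3; pooled over cases the co-localization is
decisive (t ≈ 59, p below double-precision resolution — far beyond the
p < 0.001 level). The other examples demonstrate cohort simulation, patch
QC, valley detection on a mixture with a known minimum at 0.2 (detected
0.221), and ΔΔCt fold changes (a Ct of 41.2 is called `not_expressed`).

There is also a thin CLI: `imcpatch simulate|analyze|ddct|all` (see
`imcpatch analyze --help`), which writes `results.json`, patch tables, the
density curve, and figures, embedding the resolved config and its hash.

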