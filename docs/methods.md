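# Methods

## Tangent-line classification of TF-enriched super-enhancers

### Model

Given an SE catalog and a per-base coverage track, the per-SE statistic is
the *binding density*: above-threshold signal per kilobase of SE. Both the
threshold and the final cutoff come from the same geometric construction.
Values are sorted ascending; ranks are mapped to `x = i/(N−1)` and values
to `y = (v − min)/(max − min)`, so the curve runs from (0, 0) to (1, 1).
For a convex ranked curve, the point where a line of slope 1 is tangent is
the point of maximal signed gap below the diagonal, i.e.
`argmin_i (y_i − x_i)`; this discrete argmin is what the code computes, so
it is exactly checkable against exhaustive enumeration (the test suite
does this on thousands of random monotone curves). Ties break to the
smallest index — the lowest, most inclusive threshold. Min–max scaling
(rather than divide-by-max) pins both endpoints; with a zero minimum the
two conventions coincide.

### Scale consistency of the two stages

"Above-threshold signal" only typechecks if the stage-1 threshold lives on
the same scale as the per-base depths that stage 2 counts. The stage-1
curve therefore ranks the *pooled per-base depths* of all catalog bases by
default (`threshold_level="base-depth"`), returning a depth-scale
threshold. A variant ranking per-SE total signal
(`threshold_level="se-total"`) is provided for exploring catalog-level
distributions, but its output is on the totals scale and is not a
sensible input to a per-base density. Classification uses strict
inequality (`>`) at both stages.

Two signal modes are offered because public descriptions of "counts of
reads above a threshold" are ambiguous between counting positions and
summing pileup: `depth-positions` (default) counts above-threshold bases
per kb; `depth-sum` sums their depths per kb. On binary tracks the two
coincide (densities differ by a positive constant, which min–max scaling
removes).

No smoothing is applied by default (`smooth_window=1`); a centred
moving-average hook exists for noisy density curves. The cutoff is a
geometric construction, not a hypothesis test: no p-values, no
multiple-testing correction, and no claim of statistical significance
attaches to the enriched/background split.

### What the coverage simulator emulates

`simulate_coverage` plants a known enriched set: background SEs draw
i.i.d. Poisson(λ) per-base depth (default λ = 20); enriched SEs carry a
contiguous block covering `peak_fraction` (default 0.3) of their bases at
Poisson(λ·ratio) (default ratio 10). Default catalog: 200 background + 31
enriched SEs of 800–3000 bp on a handful of synthetic chromosomes —
interval sizes on the order of constituent enhancers, which keeps tracks
compact. This reproduces the hockey-stick geometry (a long shallow ramp, a
sharp enriched elbow) but deliberately omits fragment-level read
structure: mappability gaps, GC bias, fragment-length autocorrelation,
copy-number variation, and input normalisation. Passing recovery tests
therefore shows the geometric procedure is implemented correctly and is
well-posed on sharply separated signal; it does not certify performance
on real ChIP-seq, where the elbow is softer and the threshold unit depends
on upstream processing. At planted enrichment ratios ≥ 5 with λ ≥ 20
recovery is exact at almost every seed; occasionally a background SE sits
exactly at the tangent boundary and is called (one false positive in ~200,
observed at a minority of seeds). As the ratio approaches 1 the called set
overlaps the planted labels only at chance rate.

## Binding and kinetics

**EMSA.** Per lane, fraction bound = `[1 − free/total] × 100`, with total
taken from the free band of the zero-protein lane; out-of-range
intensities (quantification noise) are clipped with a warning rather than
rejected. The Hill fit is bounded least squares on
`f = Bmax·X^h/(KD^h + X^h)` with Bmax fixed to 1 by default (apparent-KD
convention for true fractions); KD is optimised on a log scale,
`h ∈ (0.1, 10]`, initial KD = the concentration whose fraction is nearest
0.5, initial h = 1.

**BLI.** The sequential analysis fits the association phase to
`Y = Y0 + A(1 − e^(−kobs t))` and the dissociation phase to
`Y = Y0 + A·e^(−kd t)` (phase time re-zeroed at each phase start), then
applies `ka = (kobs − kd)/[Analyte]`, `KD = kd/ka`. `kobs ≤ kd` is an
error ("no net association"). When a dissociation trace decays by less
than 1% over the window, kd is flagged lower-bound-only: amplitude and
plateau are confounded. A global 1:1 fit (shared ka, kd, Rmax across
analyte concentrations, `Req = Rmax·C/(C + kd/ka)`) is available as
`mode="global"`; both routes are exposed because published KDs come from
either, and they agree exactly on noiseless 1:1 data. Rates are optimised
in log space over a small fixed grid of starts, so fits are deterministic.

**FRAP.** Correction is `(ROI − bg)/(ref − bg)` normalised to the
pre-bleach mean of the same ratio; the output pre-bleach mean is exactly 1
and any common multiplicative drift captured by the reference cancels
exactly. `ref ≤ bg` at any frame is an error. The post-bleach segment
(time re-zeroed at the bleach) is fitted to the rising double exponential
`F(t) = F0 + A1(1 − e^(−t/τ1)) + A2(1 − e^(−t/τ2))`, components ordered
τ1 ≤ τ2, amplitudes bounded ≥ 0, with a deterministic multi-start over
τ-ratio/amplitude-split initialisations. The single reported τ is the
amplitude-weighted mean `(A1τ1 + A2τ2)/(A1 + A2)` — the parameterisation
of a "reported tau" varies across software, and the weighted mean is the
convention here; both components are always reported alongside it. When
the minor amplitude is < 1% of the major, the model refits a single
exponential (the second component is unidentifiable at that level).
Mobile fraction = `(A1 + A2)/(1 − F0)`.

## Droplet quantification and colocalization

The mask is `intensity ≥ threshold` (inclusive, matching common
particle-analysis tools); default threshold 100 is only meaningful for
images scaled like the calibration images it came from (maximum intensity
of protein-alone controls) — it is a parameter, not a constant. Particles
are 8-connected components (4-connected optional); a physical size cut
(e.g. "2 × 2 μm²" → area ≥ 4 μm²) requires the pixel size. Touching
droplets merge — no watershed splitting — so counts are lower bounds in
crowded fields; the disk generator can place overlapping disks to exercise
exactly this. Colocalization is plain Pearson correlation over ROI pixels
with no thresholding; constant channels are an error (undefined
correlation).

## ΔΔCt

Replicate Cts are averaged on the Ct scale within (sample, gene);
ΔCt = Ct(target) − Ct(reference) per sample, ΔΔCt versus the mean control
ΔCt, fold = 2^−ΔΔCt. Per-sample folds feed the SEM. Amplification
efficiency is assumed to be 2 per cycle for all genes (no Pfaffl
correction); plate offsets cancel within a sample by construction.

## Numerical choices and limitations

* All fitters use `scipy.optimize.least_squares` with tight tolerances
  (1e-15) and bounded parameters; any multi-start is over a fixed grid, so
  results are bit-reproducible.
* Noiseless synthetic data are recovered to ≤ 1e-6 relative error by every
  fitter (asserted in the test suite); under titration noise σ = 0.02 the
  median relative KD error over 50 seeds is a few percent.
* The demo and the acceptance script derive all stage seeds from one
  integer by fixed offsets; a given seed yields byte-identical output
  bundles.
* Problem sizes in tests and the acceptance script (231 SEs of ≤ 3 kb,
  ~600-point traces, 256² images) are chosen to keep the full suite
  around half a minute while leaving every statistical claim testable at
  its stated tolerance.
* bedGraph overlaps are rejected, not summed; chromosome names are
  matched verbatim (a warning lists unmatched names). BAM/FASTQ input,
  peak calling and de-novo SE calling (ROSE-style stitching) are out of
  scope, as are mass-transport/bivalent BLI models and 3-D or time-lapse
  droplet tracking.
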