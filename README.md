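# tfse

Toolkit for asking, quantitatively, whether a transcription factor (TF) is
*enriched* at particular super-enhancers (SEs), and for the biophysical
measurements that typically accompany that question in studies of
transcriptional condensates: equilibrium and kinetic binding constants,
fluorescence-recovery kinetics, droplet (condensate) statistics from
microscopy, and qPCR fold changes.

It is aimed at genomics/biophysics researchers who have an SE catalog
(BED), a ChIP-seq coverage track (bedGraph), and bench measurements
(EMSA titrations, BLI sensorgrams, FRAP traces, fluorescence images, Ct
tables), and want a reproducible, scriptable version of the analyses that
are usually done by hand in Prism/ImageJ.

## The core procedure: slope-1 tangent classification

SE signal distributions are hockey-stick shaped: most SEs carry modest TF
signal, a small tail carries a lot. The classifier separates the tail
geometrically, in two stages:

1. **Read threshold.** Every per-base ChIP-seq depth inside the catalog is
   ranked ascending; rank and value axes are min–max scaled to [0, 1]; the
   threshold is the unscaled depth at the point where a line of slope 1 is
   tangent to the curve — on a discrete convex curve, exactly
   `argmin(y_scaled − x_scaled)`.
2. **Binding density.** Each SE's density = (number of bases with depth
   strictly above the threshold) / (SE length in kb). Densities are ranked
   and scaled the same way, and SEs strictly above the slope-1 tangent
   point of that curve are called **TF-enriched**.

The cutoff is geometric, not a statistical test. Also included:

* Hill fits of EMSA fraction-bound titrations, `f = Bmax·X^h/(KD^h + X^h)`
  with Bmax fixed to 1 (so `f(KD) = 1/2` for any `h`);
* BLI 1:1 kinetics — `Y = Y0 + A(1 − e^(−kobs·t))` (association),
  `Y = Y0 + A·e^(−kd·t)` (dissociation), `ka = (kobs − kd)/[Analyte]`,
  `KD = kd/ka` — plus a global 1:1 fit across analyte concentrations;
* FRAP correction ((ROI − bg)/(ref − bg), normalised to the pre-bleach
  mean) and a rising double-exponential recovery fit with an
  amplitude-weighted reported τ;
* threshold-and-particle droplet analysis and Pearson colocalization;
* 2^−ΔΔCt relative expression;
* seeded synthetic-data generators for every input, with ground truth.

## Worked example

```python
from tfse import SimulationSpec, simulate_coverage, run_enrichment

sim = simulate_coverage(SimulationSpec(seed=1))   # 200 background + 31 enriched SEs
res = run_enrichment(sim.records, sim.track)
print(f"read threshold {res.read_threshold:g} at "
      f"({res.threshold_xy[0]:.2f}, {res.threshold_xy[1]:.2f})")
print(f"{res.n_enriched}/{len(res.table)} SEs enriched; "
      f"mean density {res.mean_density_enriched:.1f} vs "
      f"{res.mean_density_background:.1f} per kb")
print(set(res.enriched_ids) == sim.enriched_ids)
```

prints

```
read threshold 31 at (0.95, 0.11)
31/231 SEs enriched; mean density 305.4 vs 8.0 per kb
True
```

The threshold (31) is the per-base depth at the tangent point of the
ranked signal curve; the tangent coordinates say 95% of bases lie below
it at 11% of the depth range — the elbow of the hockey stick. All 31
planted SEs are recovered with no false positives.

The same pipeline from the shell:

```bash
tfse simulate coverage --seed 1 --out demo/
tfse classify --se-bed demo/ses.bed --coverage demo/coverage.bedgraph \
              --out demo/enrichment.tsv --report demo/report.json
tfse demo --seed 1 --out demo-all/   # every stage end to end
```

Coordinates are 0-based half-open (BED convention) throughout.

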