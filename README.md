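# pfvcat

Post-GWAS prioritization of **p**otential putative **f**unctional
**v**ariants in disease association regions, packaged as a tested,
reusable pipeline and exercisable end-to-end on synthetic data with known
ground truth.

GWAS report sentinel "tagSNPs" that usually proxy for unobserved causal
variants through linkage disequilibrium (LD). `pfvcat` implements the
standard integrative strategy for narrowing each region down — developed
here around psoriasis association regions and immune-cell epigenomes, but
agnostic to trait and tissue:

1. **LD expansion** — each tagSNP is expanded to every variant in a 1 Mb
   window with `r² ≥ 0.8` in a phased reference panel, computed by direct
   haplotype counting: `r² = D²/(p₁(1−p₁)p₂(1−p₂))`, `D = p₁₂ − p₁p₂`.
2. **Matched-null enrichment** — the associated variant set (AVS; one LD
   block per tag) is scored against a peak track as the number of blocks
   with ≥ 1 variant in a peak. The null is a set of matched random variant
   sets (MRVS): block-by-block resamples from an LD-block pool matched on
   MAF, TSS proximity, and block size. The p-value is empirical with
   add-one smoothing, `p = (1 + #{null ≥ obs})/(1 + n_mrvs)`, the fold is
   observed over null mean, and Bonferroni adjustment multiplies by the
   number of tracks tested.
3. **Functional categorization** — correlated SNPs overlapping ≥ 1 of the
   five core histone marks (or a coding exon) are PFVs, partitioned by a
   first-match priority: exonic → promoter (H3K4me3 within −1000/+100 bp
   of a TSS, strand-aware) → enhancer (H3K27ac/H3K4me1) → transcribed
   (H3K36me3) → repressed (H3K27me3).
4. **Motif disruption** — each allele of a variant is scored against TF
   position weight matrices as a sum of per-position log₂ odds, maximized
   independently over all motif placements covering the variant and both
   strands; `delta = alt − ref` quantifies the allele's effect on
   predicted binding.
5. **Causal-list overlap** — the PFV arm and the non-PFV background arm
   are compared for overlap with a known-causal-variant list by a pooled
   two-proportion z test (a label-permutation test is reported alongside).

A first-class synthetic-data module generates phased haplotype panels with
controlled block LD, peak tracks with a planted fraction of covered
blocks, TSS/exon annotations, JASPAR motifs, and causal lists — so every
stage can be validated against ground truth.

## Worked example

```python
from pfvcat import (SimConfig, simulate_panel, expand_all,
                    build_null_pool, build_mrvs, enrichment_test)
from pfvcat.simulate import simulate_tracks, simulate_tss

cfg = SimConfig(n_blocks=20, n_decoy_blocks=200, n_haplotypes=200,
                snps_per_block=6, target_r2=0.95,
                peak_rate_bg=0.02, planted_block_fraction=0.5, seed=3)
sim = simulate_panel(cfg)
tss = simulate_tss(cfg, sim.blocks)
avs = expand_all(sim.panel, sim.tags, tss=tss)
pool = build_null_pool(sim.panel, tss, avs.blocks)
mrvs = build_mrvs(avs.blocks, pool, n_mrvs=500, seed=4)
track, planted = simulate_tracks(cfg, sim.avs_blocks)
res = enrichment_test(avs.blocks, mrvs, track, n_tracks_family=5)
print(res.observed, round(res.fold, 2), res.p_empirical)
```

prints

```
11 6.29 0.001996003992015968
```

— 11 of the 20 AVS blocks fall in peaks (10 were planted, one more by
background chance), 6.3-fold above the matched-null mean of 1.75, with an
empirical p of 0.002 (its minimum possible value here is 1/501): the test
recovers the planted signal. The `examples/` directory has one short
script per capability (simulation, LD expansion, enrichment,
categorization, motif disruption, overlap test).

A thin CLI wraps the same functions:

```bash
pfvcat simulate --out inputs/ --seed 42
pfvcat run-all --out run/ --seed 42
```

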