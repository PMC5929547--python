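# Methods

## The prioritization model

`pfvcat` treats a GWAS association region as an LD block: the reported
tagSNP plus every variant correlated with it at `r² ≥ r2_min` (default
0.8) inside a window of `window_bp` (default 1 Mb) centered on the tag.
r² is computed from phased haplotypes by direct counting — no EM step —
using integer arithmetic so perfect LD is exactly 1.0. The choice of a
*centered* window means ± 500 kb around the tag position.

### Enrichment against feature tracks

The associated variant set (AVS) is the list of LD blocks for all tags.
Against one feature track (a set of peaks), the AVS score is the
block-level indicator sum: a block counts once if any member variant lies
inside any peak, however many members overlap. A variant at 1-based
position `p` overlaps a 0-based half-open peak `[start, end)` iff
`start < p ≤ end`; this conversion happens in exactly one predicate.

The null is a collection of `n_mrvs` matched random variant sets. The
candidate pool contains one LD block per *distinct correlated set* among
panel variants that are neither AVS members nor in LD (`r² ≥ r2_min`)
with one; each set is represented by the block seeded at its positional
medoid, the central variant of the clique, so that covariates (tag MAF,
tag-to-nearest-TSS distance, member count) are always measured from one
canonical tag. Matching tolerances default to `|ΔMAF| ≤ 0.02`,
`|Δlog10(TSS distance + 1)| ≤ 0.25`, and `|Δsize| ≤ max(1, 10% of the
AVS block size)`: exact block-by-block identity is unattainable in a
finite pool, so the tolerances are explicit, logged, and configurable.
Replicates are drawn independently (with replacement across replicates,
without replacement within one), deterministically under a seed.

The p-value is empirical with add-one smoothing,

    p = (1 + #{null ≥ observed}) / (1 + n_mrvs),

which can never return 0 (minimum `1/(n_mrvs+1)`) and is assumption-free
under exchangeability. A normal-approximation p from the null mean and SD
is reported alongside for comparison but is never used for decisions; the
Box–Cox-style transformation some enrichment packages apply is
deliberately out of scope. The fold is `observed / max(mean(null), 0.5)`
— the 0.5 floor guards division by zero on degenerate tracks. Bonferroni
adjustment multiplies p by the number of tracks tested in one family
(e.g. the 5 histone marks, or a panel of TF tracks).

Because the block score is an integer and `≥` resolves ties against the
alternative, the empirical p is conservative (superuniform) on discrete
scores; see "calibration studies" below for how the validation handles
this.

### Functional categorization

A correlated SNP is a PFV when it overlaps ≥ 1 of the five core histone
marks (H3K4me3, H3K27ac, H3K4me1, H3K36me3, H3K27me3) in the chosen cell
type, or falls in a coding exon. Categories are assigned first-match:

1. exonic; 2. promoter = H3K4me3 ∧ within the promoter window; 3.
enhancer = H3K27ac ∨ H3K4me1; 4. transcribed = H3K36me3; 5. repressed =
H3K27me3.

The promoter window (−1000/+100 bp around the TSS) is strand-aware:
upstream means 5′ of the gene. The −/+ notation around a TSS
conventionally follows gene orientation, so this is the default; the
window is configurable. One corner case is genuinely ambiguous: a variant
whose *only* mark is H3K4me3 but which lies outside every promoter window
satisfies the PFV definition yet no category rule. Such variants are kept
as PFVs, assigned `promoter` with the qualifier `outside_tss_window`, and
reported separately — the two definitions conflict and the conflict is
surfaced rather than silently resolved. With this rule the five category
counts always partition the PFV set (a tested invariant). A variant
belonging to several blocks is attributed to the tag with the highest r².

### Motif disruption

A PWM stores per-position base probabilities; pseudocounts are folded in
at load time. The convention is: cell `b` at each position receives
`pseudocount × background_b / 0.25` added counts, i.e. `pseudocount` is
counts-per-cell at uniform background (default 0.8, so a zero count never
produces −∞). A window scores `Σ log2(P_pwm(base)/P_bg(base))`; the
background defaults to uniform and is configurable — no genomic
background model is bundled.

For a variant, each allele's score is maximized *independently* over all
motif placements covering the variant position and over both strands
(reverse complement), with deterministic tie-breaking (lower offset, then
+ strand). Independent per-allele maximization follows the convention of
allele-disruption scanners such as motifbreakR: each allele is allowed
its own best binding register. `delta = alt − ref`; the effect is
`strong` when `|delta| ≥ strong_threshold` (default 1.0 log₂-odds units,
a two-fold odds change) and the better allele scores above background,
`weak` for smaller nonzero changes, `none` otherwise.

### Causal-list overlap

The PFV arm and the background arm (correlated SNPs that are not PFVs)
are compared for overlap with an external causal-variant rsID list by the
pooled two-proportion z test with a two-sided normal tail; degenerate
pooled variance returns z = 0, p = 1. A label-permutation test
(hypergeometric resampling of causal labels over the pooled arms) is
computed alongside, because a z statistic and a normal-tail p can
disagree at small counts and reporting both surfaces any such
inconsistency instead of hiding it.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline consumes:

- **Block LD.** Each region is a block of `snps_per_block` SNPs on one
  synthetic chromosome. The tag column is drawn at an exact MAF; members
  copy the tag and exchange alleles on
  `a = round(n·p·q·(1−√target_r2))` haplotypes in each direction, which
  preserves the allele frequency exactly and realizes
  `r = 1 − a/(n·p·q)` up to the rounding of `a`. This balanced exchange
  was chosen over independent per-haplotype flips because it gives direct
  control of realized r² at *every* MAF (a flip probability calibrated
  for MAF 0.5 under-delivers r² at low MAF and makes realized block sizes
  unstable). Blocks are ≥ 2 Mb apart, so inter-block r² is ≈ 0 (tested).
- **Decoy blocks.** Beyond the AVS blocks, the panel carries
  `n_decoy_blocks` decoys whose covariates mirror the AVS blocks
  cyclically (tag MAF within ±0.005, TSS offset within ±0.1 log10,
  identical member count), emulating the genome-wide supply of candidate
  null blocks a real reference panel provides. Without covariate-matched
  decoys a finite pool starves the MRVS matching.
- **Peak tracks.** Background peaks arrive as a homogeneous process at
  `peak_rate_bg` per kb, materialized only within a peak-width margin of
  the simulated blocks (an exact thinning: farther peaks can overlap no
  variant). Additionally `round(planted_block_fraction × n_blocks)` AVS
  blocks receive one peak covering a member variant; the planted block
  ids are returned as ground truth. Planted fraction 1 with zero
  background forces the AVS score to its maximum.
- **TSS, exons, PWMs, contexts, causal lists.** One gene per block at
  the block's mirrored TSS offset from its tag; exons covering a variant
  in a configurable fraction of blocks; PWMs with Dirichlet(0.5) columns;
  variant contexts with the ref/alt allele injected at the center of a
  random sequence; causal lists containing `round(frac × n)` ids per arm
  (a `stochastic` mode includes each id with probability `frac`, used for
  calibration studies that need sampling noise — with deterministic
  rounded counts the test statistic would be a constant across seeds).

Every generator is fully deterministic under its seed.

**What the generator does not emulate:** recombination-map structure and
LD decay (inter-block LD is exactly zero by construction, not merely
small); allele-frequency spectra and population structure; peak-width and
peak-density heterogeneity of real ChIP-seq; clustering of genes and
variants; genome sequence (motif contexts are random). Passing tests
therefore demonstrate that the *statistical machinery* is correct and
calibrated under its own assumptions, not that any specific biological
catalog is reproduced — the real analysis additionally depends on
external reference panels, consolidated epigenome peak calls, and a
published causal-variant list.

## Default study conditions

`SimConfig` defaults are a desk-scale rendition of the real analysis's
shape: 500 phased haplotypes (reference panels carry ~500–750 per
population), 20 tag blocks standing in for the 75 psoriasis regions, 12
SNPs per block at within-block `target_r2 = 0.9`, MAF ∈ (0.1, 0.5)
(common variants), background peak rate 0.02/kb with 600 bp peaks, and
half the blocks planted. The end-to-end pipeline default uses
`n_mrvs = 200` (the real analysis used 1,000; the CLI default is 1,000,
the orchestrated run uses 200 to keep a full run around a second).

The repeated-run validation studies use their own designs, chosen by
pilot power analysis of the study itself and then frozen:

- **Null calibration** (planted fraction 0): 60 AVS blocks, 10× decoy
  pool, 200 haplotypes, 6 SNPs/block at `target_r2 = 0.95`, background
  rate 0.145/kb (≈ 0.5 per-block hit probability), 150 MRVS, 200 seeded
  runs, KS test against uniform at α = 0.01. The design needs this many
  blocks so the integer score has wide support (ties make the add-one p
  conservative) and this many matched candidates per block so the
  replicate null spread tracks the marginal spread; with few candidates
  the p-value distribution is visibly overdispersed.
- **Two-proportion calibration:** equal overlap fractions 0.2 on two
  arms of 800 ids, stochastic inclusion, 600 seeded draws, KS at α = 0.01.
- **Planted-signal recovery:** planted fraction 0.5, 20 blocks, low
  background (0.01/kb), Bonferroni family of 5; the adjusted p must fall
  below 0.05 in ≥ 80% of 100 seeded runs. Mean fold is additionally
  checked to be non-decreasing in the planted fraction over
  {0, 0.25, 0.5, 1.0} (20 runs per level).

## Numerical and design notes

- r² uses exact integer arithmetic in numerator and denominator before a
  single division, and is clipped at 1 against rounding.
- Within one MRVS replicate, hardest-to-match AVS blocks are sampled
  first so the without-replacement constraint rarely strands a block.
- The `fold` floor of 0.5 on the null mean only engages on degenerate
  (near-empty) tracks.
- Multiallelic, unphased, non-SNV and monomorphic VCF records are
  skipped with logged counts, not split or imputed: the analysis is over
  phased biallelic common SNPs.
- Chromosome names are compared verbatim ("chr1" ≠ "1"); the CLI exposes
  an explicit `--normalize-chr` flag rather than coercing silently.
- The pipeline's stages are resumable (a stage whose outputs exist is
  skipped until an upstream stage re-executes) and the whole run is
  byte-deterministic under one seed: per-stage seeds are `seed + stage
  index`, and the run log contains no timestamps.
- The gene-annotation build that defines TSS proximity is the caller's
  choice; any single-base BED6 annotation is accepted and its path is
  recorded in the run configuration.

## Known limitations

- The MRVS empirical p is conservative on heavily tied integer scores
  (small AVS, sparse tracks); the normal-approximation p reported
  alongside is *not* a remedy and can be anticonservative.
- The null pool construction assumes the panel is much larger than the
  AVS; it errors explicitly ("insufficient null pool") rather than
  degrading.
- Motif scoring has no p-value calibration against genome-wide score
  distributions; `delta` magnitudes are comparable within one PWM, not
  across PWMs.
- Exonic annotation is whatever BED the caller supplies; no genome build
  or transcript model is bundled, and protein-consequence prediction is
  out of scope.
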