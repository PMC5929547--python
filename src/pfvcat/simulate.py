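"""Synthetic inputs with known ground truth.

The generator emulates the statistical structure the pipeline consumes,
not the biology that produced it:

* **Haplotype panels with block LD.**  Each association region is a block
  of SNPs on one synthetic chromosome ("chrS").  The block's tagSNP column
  is drawn at an exact target MAF; every other member copies the tag and
  exchanges alleles on a = round(n p q (1 - sqrt(target_r2))) haplotypes in
  each direction (1->0 and 0->1), chosen uniformly at random.  The balanced
  exchange preserves the allele frequency exactly and realizes
  r = 1 - a/(n p q) to the tag up to the rounding of a, so r^2 is under
  direct control at every MAF (realized r^2 is still measured downstream,
  never assumed).  Blocks are spaced >= 2 Mb apart so inter-block LD is ~0.
* **Decoy blocks for the null pool.**  Beyond the AVS blocks the panel
  carries decoy blocks whose covariates (tag MAF, TSS offset, member
  count) mirror the AVS blocks up to small jitter, so covariate-matched
  null sampling always has candidates — mimicking the genome-wide supply
  of LD blocks a real panel provides.
* **Peak tracks with planted signal.**  Background peaks arrive at a
  homogeneous rate per kb; additionally a configurable fraction of AVS
  blocks each receive one peak covering a member variant.  The planted
  block ids are returned as ground truth.
* **TSS annotations, PWMs, variant contexts and causal-variant lists**
  round out the inputs.

Every generator is fully deterministic under its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    BASES,
    FeatureTrack,
    GeneAnnotation,
    GenomicInterval,
    HaplotypePanel,
    PWM,
    Variant,
)
from .motifs import VariantContext

CHROM = "chrS"
BLOCK_SPACING_BP = 2_500_000
FIRST_BLOCK_BP = 1_000_000


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults are a desk-scale rendition of the real study's shape: a few
    hundred phased haplotypes (the reference panels hold ~500-750 per
    population), a few dozen tag blocks standing in for the 75 psoriasis
    regions, ~10 SNPs per block at high within-block LD, and decoy blocks
    (3x the AVS) supplying the matched-null pool.
    """

    n_haplotypes: int = 500
    n_blocks: int = 20
    n_decoy_blocks: int = 60
    block_span_bp: int = 50_000
    snps_per_block: int = 12
    target_r2: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    peak_rate_bg: float = 0.02  # peaks per kb of spanned genome
    peak_width_bp: int = 600
    planted_block_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes <= 0 or self.n_haplotypes % 2 != 0:
            raise ValueError(f"n_haplotypes must be a positive even integer, got {self.n_haplotypes}")
        if not (0.0 < self.target_r2 <= 1.0):
            raise ValueError(f"target_r2 must be in (0, 1], got {self.target_r2}")
        if not (0.0 <= self.planted_block_fraction <= 1.0):
            raise ValueError("planted_block_fraction must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise ValueError("need at least one block and one SNP per block")
        if self.peak_rate_bg < 0:
            raise ValueError("peak_rate_bg must be >= 0")

    @property
    def n_total_blocks(self) -> int:
        return self.n_blocks + self.n_decoy_blocks

    def exchange_count(self, n_alt: int) -> int:
        """Haplotypes exchanged per direction for a member column.

        a = round(n p q (1 - sqrt(target_r2))) realizes r = 1 - a/(n p q).
        """
        n = self.n_haplotypes
        p = n_alt / n
        a = int(round(n * p * (1 - p) * (1.0 - math.sqrt(self.target_r2))))
        return min(a, n_alt, n - n_alt)

    def region_end(self) -> int:
        return FIRST_BLOCK_BP + self.n_total_blocks * BLOCK_SPACING_BP


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class TruthBlock:
    """Ground-truth membership of one simulated LD block."""

    block_id: int
    is_decoy: bool
    tag: Variant
    variants: list[Variant]
    tss_offset: int = 0

    @property
    def member_rsids(self) -> frozenset[str]:
        return frozenset(v.rsid for v in self.variants)


@dataclass
class SimPanelResult:
    panel: HaplotypePanel
    tags: list[Variant]  # AVS tags only
    decoy_tags: list[Variant]
    blocks: list[TruthBlock]  # AVS blocks first, then decoys

    @property
    def avs_blocks(self) -> list[TruthBlock]:
        return [b for b in self.blocks if not b.is_decoy]


def _block_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Tag MAF per block; decoys mirror AVS MAFs with <= 0.005 jitter."""
    lo, hi = cfg.maf_range
    avs = rng.uniform(lo, hi, size=cfg.n_blocks)
    mafs = list(avs)
    for d in range(cfg.n_decoy_blocks):
        base = avs[d % cfg.n_blocks]
        mafs.append(float(np.clip(base + rng.uniform(-0.005, 0.005), lo, hi)))
    return np.asarray(mafs)


def _tss_offsets(cfg: SimConfig) -> np.ndarray:
    """Signed TSS offset from each block's tag; decoys mirror AVS offsets."""
    rng = _rng(cfg.seed, 7)
    sign = rng.choice([-1, 1], size=cfg.n_blocks)
    mag = 10 ** rng.uniform(2.0, 4.5, size=cfg.n_blocks)
    avs = (sign * mag).astype(int)
    offsets = list(avs)
    for d in range(cfg.n_decoy_blocks):
        base = avs[d % cfg.n_blocks]
        jitter = 10 ** rng.uniform(-0.1, 0.1)
        offsets.append(int(math.copysign(max(1, abs(base) * jitter), base)))
    return np.asarray(offsets)


def simulate_panel(cfg: SimConfig) -> SimPanelResult:
    """Generate the phased haplotype panel and its tagSNPs."""
    rng = _rng(cfg.seed, 1)
    mafs = _block_mafs(cfg, rng)
    tss_offsets = _tss_offsets(cfg)
    n_hap = cfg.n_haplotypes
    sites: list[Variant] = []
    rows: list[np.ndarray] = []
    blocks: list[TruthBlock] = []
    for b in range(cfg.n_total_blocks):
        is_decoy = b >= cfg.n_blocks
        start = FIRST_BLOCK_BP + b * BLOCK_SPACING_BP
        positions = np.sort(
            rng.choice(cfg.block_span_bp, size=cfg.snps_per_block, replace=False)
        ) + start
        tag_idx = cfg.snps_per_block // 2
        n_alt = int(round(mafs[b] * n_hap))
        n_alt = min(max(n_alt, 1), n_hap // 2)  # keep folded MAF in (0, 0.5]
        tag_col = np.zeros(n_hap, dtype=np.uint8)
        tag_col[rng.choice(n_hap, size=n_alt, replace=False)] = 1
        block_vars: list[Variant] = []
        tag_variant: Optional[Variant] = None
        for s in range(cfg.snps_per_block):
            if s == tag_idx:
                col = tag_col
            else:
                a = cfg.exchange_count(n_alt)
                col = tag_col.copy()
                ones = np.flatnonzero(tag_col == 1)
                zeros = np.flatnonzero(tag_col == 0)
                col[rng.choice(ones, size=a, replace=False)] = 0
                col[rng.choice(zeros, size=a, replace=False)] = 1
            freq = float(col.mean())
            maf = min(freq, 1.0 - freq)
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            prefix = "rsD" if is_decoy else "rs"
            v = Variant(
                rsid=f"{prefix}{b:03d}_{s:02d}",
                chrom=CHROM,
                pos=int(positions[s]),
                ref=str(ref),
                alt=str(alt),
                maf=float(maf),
            )
            sites.append(v)
            rows.append(col)
            block_vars.append(v)
            if s == tag_idx:
                tag_variant = v
        assert tag_variant is not None
        blocks.append(
            TruthBlock(block_id=b, is_decoy=is_decoy, tag=tag_variant,
                       variants=block_vars, tss_offset=int(tss_offsets[b]))
        )
    panel = HaplotypePanel(sites=sites, matrix=np.vstack(rows))
    return SimPanelResult(
        panel=panel,
        tags=[bl.tag for bl in blocks if not bl.is_decoy],
        decoy_tags=[bl.tag for bl in blocks if bl.is_decoy],
        blocks=blocks,
    )


def simulate_tracks(
    cfg: SimConfig,
    avs_blocks: Sequence[TruthBlock],
    track_id: str = "synthetic:mark",
    stream: int = 2,
) -> tuple[FeatureTrack, list[int]]:
    """One peak track: homogeneous background plus planted AVS coverage.

    Exactly ``round(planted_block_fraction * len(avs_blocks))`` AVS blocks
    receive a peak covering one of their member variants.  Returns the
    track and the planted block ids (ground truth).
    """
    rng = _rng(cfg.seed, stream)
    track = FeatureTrack(track_id)
    w = cfg.peak_width_bp
    # Background peaks arrive as a homogeneous process at peak_rate_bg per kb,
    # but are materialized only within a peak-width margin of each block span:
    # a peak farther away can overlap no variant, so the restriction is an
    # exact thinning with identical overlap statistics.
    i = 0
    for b in range(cfg.n_total_blocks):
        band_lo = max(0, FIRST_BLOCK_BP + b * BLOCK_SPACING_BP - w)
        band_hi = FIRST_BLOCK_BP + b * BLOCK_SPACING_BP + cfg.block_span_bp + w
        n_bg = int(rng.poisson(cfg.peak_rate_bg * (band_hi - band_lo) / 1000.0))
        starts = np.sort(rng.integers(band_lo, band_hi - 1, size=n_bg))
        for s in starts:
            track.add(GenomicInterval(CHROM, int(s), int(s) + w, name=f"bg{i:05d}"))
            i += 1
    n_planted = int(round(cfg.planted_block_fraction * len(avs_blocks)))
    planted_idx = sorted(
        rng.choice(len(avs_blocks), size=n_planted, replace=False).tolist()
    )
    planted_ids = []
    for i in planted_idx:
        blk = avs_blocks[i]
        v = blk.variants[int(rng.integers(len(blk.variants)))]
        start = max(0, v.pos - 1 - w // 2)
        track.add(GenomicInterval(CHROM, start, start + w, name=f"planted{blk.block_id:03d}"))
        planted_ids.append(blk.block_id)
    return track, planted_ids


def simulate_tss(
    cfg: SimConfig, blocks: Optional[Sequence[TruthBlock]] = None
) -> list[GeneAnnotation]:
    """One gene per block, at the block's mirrored TSS offset from its tag.

    Offsets are anchored on the tag positions so that mirrored decoy blocks
    reproduce the AVS blocks' TSS-distance covariate up to small jitter.
    When ``blocks`` is omitted the panel layout is regenerated from the
    config (the generators are deterministic under the seed).
    """
    if blocks is None:
        blocks = simulate_panel(cfg).blocks
    rng = _rng(cfg.seed, 8)
    genes = []
    for blk in blocks:
        tss = max(1, blk.tag.pos + blk.tss_offset)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gene_id=f"g{blk.block_id:03d}", chrom=CHROM,
                                    tss=tss, strand=strand))
    return genes


def simulate_exons(
    cfg: SimConfig, blocks: Sequence[TruthBlock], exon_fraction: float = 0.1,
    exon_width: int = 200, stream: int = 9,
) -> FeatureTrack:
    """Coding-exon stand-in: an exon covering one variant in a block fraction."""
    rng = _rng(cfg.seed, stream)
    track = FeatureTrack("exons")
    n = int(round(exon_fraction * len(blocks)))
    for i in sorted(rng.choice(len(blocks), size=n, replace=False).tolist()):
        blk = blocks[i]
        v = blk.variants[int(rng.integers(len(blk.variants)))]
        start = max(0, v.pos - 1 - exon_width // 2)
        track.add(GenomicInterval(CHROM, start, start + exon_width, name=f"exon{blk.block_id:03d}"))
    return track


def simulate_pwms(n: int, length: int, seed: int) -> list[PWM]:
    """Random PWMs with concentrated columns (Dirichlet alpha = 0.5)."""
    rng = _rng(seed, 10)
    pwms = []
    for i in range(n):
        matrix = rng.dirichlet(np.full(4, 0.5), size=length)
        pwms.append(PWM(motif_id=f"M{i:03d}", matrix=matrix))
    return pwms


def simulate_contexts(
    variants: Sequence[Variant], half_width: int = 15, seed: int = 0
) -> list[VariantContext]:
    """Random sequence contexts with the ref/alt allele injected at center."""
    rng = _rng(seed, 11)
    out = []
    for v in variants:
        seq = rng.choice(list(BASES), size=2 * half_width + 1)
        ref_seq = "".join(seq[:half_width]) + v.ref + "".join(seq[half_width + 1:])
        alt_seq = ref_seq[:half_width] + v.alt + ref_seq[half_width + 1:]
        out.append(VariantContext(variant=v, ref_seq=ref_seq, alt_seq=alt_seq))
    return out


def simulate_causal_list(
    pfv_ids: Sequence[str],
    bg_ids: Sequence[str],
    overlap_frac_pfv: float,
    overlap_frac_bg: float,
    seed: int,
    stochastic: bool = False,
) -> list[str]:
    """A known-causal-variant rsID list with controlled arm overlap.

    Deterministic mode takes exactly round(frac * n) ids per arm; the
    stochastic mode includes each id independently with probability frac
    (used for sampling-noise calibration studies).
    """
    if set(pfv_ids) & set(bg_ids):
        raise ValueError("pfv_ids and bg_ids must be disjoint")
    for f in (overlap_frac_pfv, overlap_frac_bg):
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"overlap fraction must be in [0, 1], got {f}")
    rng = _rng(seed, 12)
    causal: list[str] = []
    for ids, frac in ((list(pfv_ids), overlap_frac_pfv), (list(bg_ids), overlap_frac_bg)):
        if stochastic:
            picks = [i for i in ids if rng.random() < frac]
        else:
            k = int(round(frac * len(ids)))
            picks = [ids[j] for j in sorted(rng.choice(len(ids), size=k, replace=False).tolist())]
        causal.extend(picks)
    return causal


MARK_STREAMS = {"H3K4me3": 20, "H3K27ac": 21, "H3K4me1": 22, "H3K36me3": 23, "H3K27me3": 24}


def write_fixture_dir(cfg: SimConfig, outdir: str | Path) -> dict:
    """Materialize a full input directory: panel.vcf, tags.tsv, five mark
    tracks, exons.bed, tss.bed, motifs.jaspar and truth.json.
    """
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_panel(cfg)
    fio.write_vcf(sim.panel, outdir / "panel.vcf",
                  chrom_lengths={CHROM: cfg.region_end() + 100_000})
    with open(outdir / "tags.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tmaf\n")
        for t in sim.tags:
            fh.write(f"{t.rsid}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.maf:.6f}\n")
    planted: dict[str, list[int]] = {}
    for mark, stream in MARK_STREAMS.items():
        track, ids = simulate_tracks(cfg, sim.avs_blocks, track_id=f"E038:{mark}",
                                     stream=stream)
        fio.write_bed(list(track.intervals()), outdir / f"track_{mark}.narrowPeak")
        planted[mark] = ids
    exons = simulate_exons(cfg, sim.avs_blocks)
    fio.write_bed(list(exons.intervals()), outdir / "exons.bed")
    fio.write_tss_bed(simulate_tss(cfg, sim.blocks), outdir / "tss.bed")
    fio.write_jaspar(simulate_pwms(8, 8, cfg.seed), outdir / "motifs.jaspar")
    truth = {
        "config": {**asdict(cfg), "maf_range": list(cfg.maf_range)},
        "planted_blocks": planted,
        "avs_block_members": {b.tag.rsid: sorted(b.member_rsids) for b in sim.avs_blocks},
        "decoy_tags": [t.rsid for t in sim.decoy_tags],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
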