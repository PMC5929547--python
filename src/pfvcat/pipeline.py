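"""End-to-end orchestration: simulate -> expand -> enrich -> prioritize ->
motifs -> overlap-test, with resumable stages and full determinism.

One global seed drives everything; each stage uses seed + stage_index.  A
stage is skipped when its primary outputs already exist, but once any
stage re-executes, every downstream stage re-executes too (their inputs
may have changed).  The resolved configuration and a deterministic run log
(no timestamps) are written into the output directory, so two runs with
the same seed into fresh directories are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as fio
from .assoc import overlap_test, permutation_overlap_test
from .core import CORE_MARKS, Variant
from .enrichment import build_mrvs, build_null_pool, enrichment_test
from .ld import expand_all
from .prioritize import build_pfv_catalog
from .motifs import scan_catalog
from .simulate import SimConfig, simulate_causal_list, simulate_contexts, write_fixture_dir

STAGES = ("simulate", "expand", "enrich", "prioritize", "motifs", "overlap_test")


@dataclass
class RunConfig:
    """All tunables of every stage; serializes to/from a flat JSON file."""

    seed: int = 0
    # synthetic inputs
    n_haplotypes: int = 500
    n_blocks: int = 20
    n_decoy_blocks: int = 60
    block_span_bp: int = 50_000
    snps_per_block: int = 12
    target_r2: float = 0.9
    maf_low: float = 0.1
    maf_high: float = 0.5
    peak_rate_bg: float = 0.02
    planted_block_fraction: float = 0.5
    # LD expansion
    window_bp: int = 1_000_000
    r2_min: float = 0.8
    # enrichment
    n_mrvs: int = 200
    maf_tol: float = 0.02
    tss_log10_tol: float = 0.25
    size_tol: Optional[int] = None
    # prioritization
    promoter_upstream: int = -1000
    promoter_downstream: int = 100
    # motifs
    strong_threshold: float = 1.0
    context_half_width: int = 15
    # causal-list ground truth
    causal_frac_pfv: float = 0.5
    causal_frac_bg: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_min <= 1.0):
            raise ValueError(f"r2_min must be in (0, 1], got {self.r2_min}")
        if self.window_bp <= 0 or self.n_mrvs < 1:
            raise ValueError("window_bp and n_mrvs must be positive")
        # SimConfig re-validates the synthetic parameters
        self.sim_config()

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_haplotypes=self.n_haplotypes,
            n_blocks=self.n_blocks,
            n_decoy_blocks=self.n_decoy_blocks,
            block_span_bp=self.block_span_bp,
            snps_per_block=self.snps_per_block,
            target_r2=self.target_r2,
            maf_range=(self.maf_low, self.maf_high),
            peak_rate_bg=self.peak_rate_bg,
            planted_block_fraction=self.planted_block_fraction,
            seed=self.seed,
        )

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGES.index(stage)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _read_tags(path: Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [Variant(rsid=r.rsid, chrom=r.chrom, pos=int(r.pos), ref=r.ref,
                    alt=r.alt, maf=float(r.maf))
            for r in df.itertuples(index=False)]


def run_all(cfg: RunConfig, outdir: str | Path, log=None) -> Path:
    """Execute the full pipeline into ``outdir``; resumable and deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = outdir / "inputs"
    cfg.to_json(outdir / "config.json")
    log_lines: list[str] = [f"pfvcat run, seed={cfg.seed}"]
    dirty = False

    def note(msg: str) -> None:
        log_lines.append(msg)
        if log is not None:
            log(msg)

    # --- stage 1: simulate -------------------------------------------------
    if dirty or not (inputs / "truth.json").exists():
        write_fixture_dir(cfg.sim_config(), inputs)
        dirty = True
    with open(inputs / "truth.json") as fh:
        truth = json.load(fh)
    note(f"simulate: {cfg.n_blocks} AVS blocks, {cfg.n_decoy_blocks} decoys, "
         f"{cfg.n_haplotypes} haplotypes")

    # --- stage 2: expand ---------------------------------------------------
    blocks_path = outdir / "correlated_snps.tsv"
    panel, _ = fio.read_vcf_panel(inputs / "panel.vcf")
    tss = fio.read_tss_bed(inputs / "tss.bed")
    tags = _read_tags(inputs / "tags.tsv")
    expansion = expand_all(panel, tags, window_bp=cfg.window_bp,
                           r2_min=cfg.r2_min, tss=tss)
    if dirty or not blocks_path.exists():
        rows = [(v.rsid, v.chrom, v.pos, v.ref, v.alt, round(v.maf, 6))
                for v in expansion.unique_variants]
        pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt", "maf"]) \
            .to_csv(blocks_path, sep="\t", index=False)
        dirty = True
    note(f"expand: {len(expansion.blocks)} blocks, "
         f"{expansion.n_unique} unique correlated SNPs, "
         f"{len(expansion.shared_variants)} shared variants")

    # --- stage 3: enrich ---------------------------------------------------
    enrich_path = outdir / "enrichment.tsv"
    tracks = {m: fio.read_narrowpeak(inputs / f"track_{m}.narrowPeak", f"E038:{m}")
              for m in CORE_MARKS}
    if dirty or not enrich_path.exists():
        pool = build_null_pool(panel, tss, expansion.blocks,
                               r2_min=cfg.r2_min, window_bp=cfg.window_bp)
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=cfg.n_mrvs,
                          maf_tol=cfg.maf_tol, tss_log10_tol=cfg.tss_log10_tol,
                          size_tol=cfg.size_tol, seed=cfg.stage_seed("enrich"))
        rows = []
        for m in CORE_MARKS:
            res = enrichment_test(expansion.blocks, mrvs, tracks[m],
                                  n_tracks_family=len(CORE_MARKS))
            rows.append((res.track_id, res.observed, round(res.null_mean, 4),
                         round(res.null_sd, 4), round(res.fold, 4),
                         res.p_empirical, res.p_normal, res.p_adjusted))
        pd.DataFrame(rows, columns=["track", "observed", "null_mean", "null_sd",
                                    "fold", "p_empirical", "p_normal", "p_adjusted"]) \
            .to_csv(enrich_path, sep="\t", index=False)
        dirty = True
    enr = pd.read_csv(enrich_path, sep="\t")
    note("enrich: " + "; ".join(
        f"{r.track} fold={r.fold:.2f} p_adj={r.p_adjusted:.4g}"
        for r in enr.itertuples(index=False)))

    # --- stage 4: prioritize -----------------------------------------------
    catalog_path = outdir / "catalog.tsv"
    counts_path = outdir / "category_counts.json"
    exons = fio.read_narrowpeak(inputs / "exons.bed", "exons")
    records, counts = build_pfv_catalog(
        expansion.blocks, tracks, exons, tss,
        promoter_window=(cfg.promoter_upstream, cfg.promoter_downstream))
    if dirty or not catalog_path.exists() or not counts_path.exists():
        fio.write_catalog(records, catalog_path)
        with open(counts_path, "w") as fh:
            json.dump({"counts": counts, "n_pfv": len(records),
                       "n_correlated": expansion.n_unique}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")
        dirty = True
    note(f"prioritize: {len(records)} PFVs of {expansion.n_unique} correlated; "
         f"counts={counts}")

    # --- stage 5: motifs ---------------------------------------------------
    motifs_path = outdir / "motif_hits.tsv"
    pwms = fio.read_jaspar(inputs / "motifs.jaspar")
    pfv_variants = [r.variant for r in records]
    if dirty or not motifs_path.exists():
        contexts = simulate_contexts(pfv_variants, half_width=cfg.context_half_width,
                                     seed=cfg.stage_seed("motifs"))
        hits = scan_catalog(pwms, contexts, strong_threshold=cfg.strong_threshold,
                            min_effect="strong")
        rows = []
        for rsid in sorted(hits):
            for h in hits[rsid]:
                rows.append((rsid, h.motif_id, round(h.ref_score, 4),
                             round(h.alt_score, 4), round(h.delta, 4),
                             h.best_offset, h.best_strand, h.effect))
        pd.DataFrame(rows, columns=["rsid", "motif_id", "ref_score", "alt_score",
                                    "delta", "best_offset", "best_strand", "effect"]) \
            .to_csv(motifs_path, sep="\t", index=False)
        dirty = True
    n_hits = len(pd.read_csv(motifs_path, sep="\t"))
    note(f"motifs: {n_hits} strong allele-disruption hits "
         f"({len(pwms)} motifs x {len(records)} PFVs)")

    # --- stage 6: overlap-test ---------------------------------------------
    overlap_path = outdir / "overlap_test.json"
    if dirty or not overlap_path.exists():
        pfv_ids = sorted(r.variant.rsid for r in records)
        bg_ids = sorted(v.rsid for v in expansion.unique_variants
                        if v.rsid not in set(pfv_ids))
        causal = simulate_causal_list(pfv_ids, bg_ids, cfg.causal_frac_pfv,
                                      cfg.causal_frac_bg,
                                      seed=cfg.stage_seed("overlap_test"))
        res = overlap_test(pfv_ids, bg_ids, causal)
        p_perm = permutation_overlap_test(res.k_pfv, res.n_pfv, res.k_bg, res.n_bg,
                                          seed=cfg.stage_seed("overlap_test"))
        with open(overlap_path, "w") as fh:
            json.dump({"n_pfv": res.n_pfv, "k_pfv": res.k_pfv,
                       "n_bg": res.n_bg, "k_bg": res.k_bg,
                       "z": res.z, "p": res.p, "p_permutation": p_perm},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        dirty = True
    with open(overlap_path) as fh:
        ov = json.load(fh)
    note(f"overlap-test: {ov['k_pfv']}/{ov['n_pfv']} PFV vs "
         f"{ov['k_bg']}/{ov['n_bg']} background, z={ov['z']:.2f} p={ov['p']:.3g}")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
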