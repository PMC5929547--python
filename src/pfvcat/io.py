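"""Readers and writers for the external formats the pipeline touches.

VCF parsing is delegated to cyvcf2 (htslib); BED-dialect tables go through
pandas; JASPAR matrices through Bio.motifs.  Every writer/reader pair is an
identity on its domain type, and coordinate conventions are preserved
verbatim: VCF positions stay 1-based, BED intervals stay 0-based half-open.
Chromosome strings are compared verbatim ("chr1" != "1"); callers that need
chr-prefix normalization opt in explicitly.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from cyvcf2 import VCF

from .core import (
    BASES,
    FeatureTrack,
    GeneAnnotation,
    GenomicInterval,
    HaplotypePanel,
    PWM,
    Variant,
)

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")

CATALOG_COLUMNS = [
    "rsid", "chrom", "pos", "ref", "alt", "tag_rsid", "r2",
    "category", "marks", "motif_hits",
]


@dataclass
class PanelReadReport:
    """Counts of records skipped while reading a VCF panel."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_unphased: int = 0
    n_monomorphic: int = 0
    n_non_snv: int = 0


def _prevalidate_vcf(path: str | Path) -> None:
    # htslib's own errors do not carry the line number; a cheap scan of the
    # POS column catches malformed coordinates with a useful message first.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            if not fields[1].isdigit():
                raise ValueError(
                    f"{path}: line {lineno}: malformed coordinate {fields[1]!r}"
                )


def read_vcf_panel(
    path: str | Path, region: Optional[str] = None
) -> tuple[HaplotypePanel, PanelReadReport]:
    """Read phased biallelic SNVs from a VCF into a haplotype panel.

    Multiallelic, unphased, non-SNV and monomorphic records are skipped and
    counted in the returned report.  ``region`` is an optional
    ``chrom:start-end`` filter (1-based, inclusive).
    """
    path = str(path)
    _prevalidate_vcf(path)
    region_chrom, region_lo, region_hi = None, None, None
    if region is not None:
        m = _REGION_RE.match(region)
        if not m:
            raise ValueError(f"malformed region {region!r}, expected chrom:start-end")
        region_chrom, region_lo, region_hi = m.group(1), int(m.group(2)), int(m.group(3))

    vcf = VCF(path)
    report = PanelReadReport()
    sites: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if region_chrom is not None and (
            rec.CHROM != region_chrom or not (region_lo <= rec.POS <= region_hi)
        ):
            continue
        if len(rec.ALT) != 1:
            report.n_multiallelic += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            report.n_non_snv += 1
            continue
        gts = rec.genotype.array()
        if gts is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} has no GT field")
        phased = gts[:, -1]
        if not phased.all():
            report.n_unphased += 1
            continue
        haps = gts[:, :-1].reshape(-1).astype(np.int64)
        if (haps < 0).any():
            report.n_unphased += 1  # missing alleles treated as unusable
            continue
        freq = haps.mean()
        if freq in (0.0, 1.0):
            report.n_monomorphic += 1
            continue
        maf = min(freq, 1.0 - freq)
        rsid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        sites.append(
            Variant(rsid=rsid, chrom=rec.CHROM, pos=rec.POS,
                    ref=rec.REF, alt=rec.ALT[0], maf=float(maf))
        )
        rows.append(haps.astype(np.uint8))
        report.n_kept += 1
    n_hap = rows[0].size if rows else 2 * len(vcf.samples)
    matrix = np.vstack(rows) if rows else np.zeros((0, n_hap), dtype=np.uint8)
    skipped = (report.n_multiallelic + report.n_unphased
               + report.n_monomorphic + report.n_non_snv)
    if skipped:
        logger.info("read_vcf_panel(%s): kept %d sites, skipped %d", path,
                    report.n_kept, skipped)
    return HaplotypePanel(sites=sites, matrix=matrix), report


def write_vcf(panel: HaplotypePanel, path: str | Path, chrom_lengths=None) -> None:
    """Write a haplotype panel as an uncompressed phased VCF."""
    n_samples = panel.n_haplotypes // 2
    sample_names = [f"S{i:04d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({v.chrom for v in panel.sites})
        for c in chroms:
            length = (chrom_lengths or {}).get(
                c, max(v.pos for v in panel.sites if v.chrom == c) + 10_000
            )
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        order = sorted(range(panel.n_sites),
                       key=lambda i: (panel.sites[i].chrom, panel.sites[i].pos))
        for i in order:
            v = panel.sites[i]
            row = panel.matrix[i]
            gts = "\t".join(f"{row[2*s]}|{row[2*s+1]}" for s in range(n_samples))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_narrowpeak(path: str | Path, track_id: str) -> FeatureTrack:
    """Read a 6-10 column BED-dialect (narrowPeak) file as a feature track.

    Intervals are stored 0-based half-open exactly as in the file; columns
    beyond chrom/start/end/name/score are ignored.
    """
    track = FeatureTrack(track_id)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return track
    if df.shape[1] < 3:
        raise ValueError(f"{path}: narrowPeak/BED needs >= 3 columns")
    for row in df.itertuples(index=False):
        try:
            start, end = int(row[1]), int(row[2])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric coordinate in record {tuple(row[:3])}"
            ) from None
        if start >= end:
            raise ValueError(f"{path}: start >= end in record {tuple(row[:3])}")
        name = str(row[3]) if df.shape[1] > 3 else "."
        score = float(row[4]) if df.shape[1] > 4 else 0.0
        track.add(GenomicInterval(chrom=str(row[0]), start=start, end=end,
                                  name=name, score=score))
    return track


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (strand column fixed to '.')."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end, x.name)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t.\n")


def read_tss_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6 TSS annotation: one record per gene, start = TSS-1, end = TSS."""
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 6:
        raise ValueError(f"{path}: TSS BED needs 6 columns (strand required)")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row[1]), int(row[2])
        if end != start + 1:
            raise ValueError(
                f"{path}: TSS record {row[3]} must be a single base (start=TSS-1, end=TSS)"
            )
        genes.append(GeneAnnotation(gene_id=str(row[3]), chrom=str(row[0]),
                                    tss=end, strand=str(row[5])))
    return genes


def write_tss_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.tss - 1}\t{g.tss}\t{g.gene_id}\t0\t{g.strand}\n")


def read_jaspar(
    path: str | Path,
    pseudocount: float = 0.8,
    background: Optional[Sequence[float]] = None,
) -> list[PWM]:
    """Read JASPAR count matrices and convert to probability PWMs."""
    with open(path) as fh:
        text = fh.read()
    with _stdio.StringIO(text) as fh:
        parsed = list(bio_motifs.parse(fh, "jaspar"))
    pwms = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        name = m.matrix_id or m.name
        pwms.append(PWM.from_counts(name, counts, pseudocount=pseudocount,
                                    background=background))
    return pwms


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            counts = np.rint(p.matrix * scale).astype(int)
            for bi, base in enumerate(BASES):
                row = " ".join(f"{c:6d}" for c in counts[:, bi])
                fh.write(f"{base}  [{row} ]\n")


def write_catalog(records, path: str | Path) -> None:
    """Write PFV records as a TSV with a deterministic (chrom, pos, rsid) order."""
    rows = []
    for r in records:
        v = r.variant
        marks = ",".join(sorted(r.marks_hit)) if r.marks_hit else "."
        hits = ";".join(
            f"{h.motif_id}:{h.delta:+.3f}:{h.effect}" for h in r.motif_hits
        ) or "."
        rows.append((v.rsid, v.chrom, v.pos, v.ref, v.alt, r.tag_rsid,
                     round(r.r2, 6), r.category, marks, hits))
    rows.sort(key=lambda t: (t[1], t[2], t[0]))
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
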