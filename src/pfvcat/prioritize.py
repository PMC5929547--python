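"""Functional categorization of correlated SNPs against five core histone marks.

A correlated SNP is a potential putative functional variant (PFV) when it
overlaps at least one of the five core histone-mark peak sets in the chosen
cell type, or falls in a coding exon.  PFVs are partitioned into five
categories by a first-match priority rule:

  1. exonic       — inside a coding exon
  2. promoter     — H3K4me3 peak AND within the promoter window around a TSS
  3. enhancer     — H3K27ac or H3K4me1 peak
  4. transcribed  — H3K36me3 peak
  5. repressed    — H3K27me3 peak

The promoter window is -1000/+100 bp around the TSS, oriented by gene
strand (upstream = 5').  A variant whose only mark is H3K4me3 but which
lies outside every promoter window is still a PFV by the marks definition;
it is assigned the promoter category with the qualifier
``outside_tss_window`` so the conflict between the two definitions is
surfaced rather than hidden, and the five category counts always partition
the PFV set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import CORE_MARKS, FeatureTrack, GeneAnnotation, LDBlock, Variant

CATEGORIES = ("exonic", "promoter", "enhancer", "transcribed", "repressed")
DEFAULT_PROMOTER_WINDOW = (-1000, 100)


@dataclass
class MarkOverlap:
    variant: Variant
    marks_hit: frozenset[str]
    in_exon: bool
    in_promoter_window: bool


@dataclass
class PFVRecord:
    """A prioritized variant with its category and supporting annotations."""

    variant: Variant
    tag_rsid: str
    r2: float
    category: str
    marks_hit: frozenset[str]
    in_exon: bool = False
    qualifier: str = ""
    motif_hits: list = field(default_factory=list)


def in_promoter_window(
    v: Variant,
    tss: Sequence[GeneAnnotation],
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> bool:
    """Strand-aware promoter-window test.

    For a + strand gene the window (-1000, +100) covers positions
    [tss-1000, tss+100]; for a - strand gene, [tss-100, tss+1000].
    """
    up, down = window
    for g in tss:
        if g.chrom != v.chrom:
            continue
        offset = v.pos - g.tss if g.strand == "+" else g.tss - v.pos
        if up <= offset <= down:
            return True
    return False


def overlap_marks(
    variants: Sequence[Variant],
    tracks: Mapping[str, FeatureTrack],
    exons: Optional[FeatureTrack],
    tss: Sequence[GeneAnnotation],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> list[MarkOverlap]:
    """Point-in-interval overlap of each variant with the five mark tracks."""
    missing = [m for m in CORE_MARKS if m not in tracks]
    if missing:
        raise ValueError(f"missing core mark tracks: {', '.join(missing)}")
    out = []
    for v in variants:
        hit = frozenset(m for m in CORE_MARKS if tracks[m].overlaps_variant(v))
        out.append(
            MarkOverlap(
                variant=v,
                marks_hit=hit,
                in_exon=bool(exons is not None and exons.overlaps_variant(v)),
                in_promoter_window=in_promoter_window(v, tss, promoter_window),
            )
        )
    return out


def categorize(o: MarkOverlap) -> Optional[str]:
    """First matching priority rule wins; None when no rule applies.

    None is returned for a variant with no overlaps at all, and for the
    edge case of an H3K4me3-only hit outside every promoter window — the
    caller decides how to surface that case.
    """
    if o.in_exon:
        return "exonic"
    if "H3K4me3" in o.marks_hit and o.in_promoter_window:
        return "promoter"
    if "H3K27ac" in o.marks_hit or "H3K4me1" in o.marks_hit:
        return "enhancer"
    if "H3K36me3" in o.marks_hit:
        return "transcribed"
    if "H3K27me3" in o.marks_hit:
        return "repressed"
    return None


def build_pfv_catalog(
    blocks: Sequence[LDBlock],
    tracks: Mapping[str, FeatureTrack],
    exons: Optional[FeatureTrack],
    tss: Sequence[GeneAnnotation],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> tuple[list[PFVRecord], dict[str, int]]:
    """PFV records for the unique correlated variants of an expanded AVS.

    Returns the records (sorted by chrom, pos, rsid) and the category
    counts; the counts always partition the record set.  A variant in
    several blocks is attributed to the tag with the highest r^2.
    """
    best: dict[str, tuple[Variant, str, float]] = {}
    for b in blocks:
        for v, r2 in b.members:
            cur = best.get(v.rsid)
            if cur is None or r2 > cur[2]:
                best[v.rsid] = (v, b.tag.rsid, r2)
    variants = [t[0] for t in sorted(best.values(),
                                     key=lambda t: (t[0].chrom, t[0].pos, t[0].rsid))]
    overlaps = overlap_marks(variants, tracks, exons, tss, promoter_window)
    records: list[PFVRecord] = []
    for o in overlaps:
        if not o.marks_hit and not o.in_exon:
            continue  # not a PFV
        cat = categorize(o)
        qualifier = ""
        if cat is None:
            # H3K4me3-only hit outside the promoter window: still a PFV by
            # the marks definition; surfaced with a qualifier.
            cat = "promoter"
            qualifier = "outside_tss_window"
        _, tag_rsid, r2 = best[o.variant.rsid]
        records.append(
            PFVRecord(variant=o.variant, tag_rsid=tag_rsid, r2=r2, category=cat,
                      marks_hit=o.marks_hit, in_exon=o.in_exon, qualifier=qualifier)
        )
    counts = Counter(r.category for r in records)
    return records, {c: counts.get(c, 0) for c in CATEGORIES}
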