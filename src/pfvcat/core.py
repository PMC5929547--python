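"""Domain types shared across the pipeline.

Coordinate conventions are strict and enforced at construction time:
variants carry 1-based positions (VCF convention); genomic intervals are
0-based half-open (BED convention).  The two meet only inside
:meth:`FeatureTrack.overlaps_variant`, where a variant at 1-based position
``p`` overlaps ``[start, end)`` iff ``start < p <= end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: The five core histone marks used for functional categorization.
CORE_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K36me3", "H3K27me3")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with 1-based coordinates and folded allele frequency."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, as in BED/narrowPeak files."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )


class FeatureTrack:
    """A named set of genomic intervals (one mark or TF in one cell type).

    Intervals may overlap each other; point lookup is deterministic.
    """

    def __init__(self, track_id: str, intervals: Iterable[GenomicInterval] = ()):
        self.track_id = track_id
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield iv.data

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside any interval.

        1-based position p hits [start, end) iff start < p <= end, i.e. the
        0-based point p-1 lies in the half-open interval.
        """
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def overlaps_variant(self, v: Variant) -> bool:
        return self.overlaps_point(v.chrom, v.pos)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its TSS and orientation."""

    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: TSS must be >= 1")


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities.

    ``matrix`` is shape (L, 4) over A,C,G,T.  ``pseudocount`` is the per-cell
    count added at load time at uniform background, redistributed by the
    background distribution for non-uniform backgrounds (cell b receives
    ``pseudocount * background[b] / 0.25``).
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be (L, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: matrix rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.8,
        background: Optional[Sequence[float]] = None,
    ) -> "PWM":
        """Convert a count matrix (L, 4) to probabilities with pseudocounts."""
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        add = pseudocount * bg / 0.25
        padded = counts + add[None, :]
        matrix = padded / padded.sum(axis=1, keepdims=True)
        return cls(motif_id=motif_id, matrix=matrix, pseudocount=pseudocount, background=bg)


@dataclass
class HaplotypePanel:
    """Phased haplotypes: ``matrix`` is (n_sites, n_haplotypes) over {0, 1}.

    0 codes the reference allele, 1 the alternate.  The column count is
    2 x n_samples and therefore even.
    """

    sites: list[Variant]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (sites x haplotypes)")
        if self.matrix.shape[0] != len(self.sites):
            raise ValueError("row count must equal number of sites")
        if self.matrix.shape[1] % 2 != 0:
            raise ValueError("haplotype count must be even (2 per sample)")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("haplotype matrix entries must be 0 or 1")
        self._index = {v.rsid: i for i, v in enumerate(self.sites)}

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    def site_index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise KeyError(f"variant {rsid} not present in panel") from None

    def sites_in_window(self, chrom: str, lo: int, hi: int) -> list[int]:
        """Indices of sites with ``lo <= pos <= hi`` on ``chrom``."""
        if not hasattr(self, "_by_chrom"):
            by: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for c in {v.chrom for v in self.sites}:
                idx = np.array([i for i, v in enumerate(self.sites) if v.chrom == c])
                pos = np.array([self.sites[i].pos for i in idx])
                order = np.argsort(pos, kind="stable")
                by[c] = (idx[order], pos[order])
            self._by_chrom = by
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        idx, pos = entry
        lo_i, hi_i = np.searchsorted(pos, [lo, hi + 1])
        return idx[lo_i:hi_i].tolist()

    def alt_frequency(self, i: int) -> float:
        return float(self.matrix[i].mean())


@dataclass
class LDBlock:
    """A tagSNP together with all its correlated variants (r2 >= threshold).

    ``members`` always contains the tag itself with r2 = 1.  ``tss_distance``
    is the absolute distance (bp) from the tag to the nearest TSS, used only
    as a matching covariate.
    """

    tag: Variant
    members: list[tuple[Variant, float]]
    tss_distance: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def tag_maf(self) -> float:
        return self.tag.maf

    @property
    def variants(self) -> list[Variant]:
        return [v for v, _ in self.members]

    @property
    def member_rsids(self) -> frozenset[str]:
        return frozenset(v.rsid for v, _ in self.members)


def nearest_tss_distance(chrom: str, pos: int, tss: Sequence[GeneAnnotation]) -> float:
    """Absolute bp distance from a 1-based position to the nearest TSS."""
    dists = [abs(pos - g.tss) for g in tss if g.chrom == chrom]
    if not dists:
        return float("inf")
    return float(min(dists))
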