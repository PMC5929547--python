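"""Pairwise LD from phased haplotypes and tagSNP block expansion.

r-squared is computed by direct haplotype counting (no EM step), which is
exact for phased panels:

    D   = p_ij - p_i * p_j
    r^2 = D^2 / (p_i (1 - p_i) p_j (1 - p_j))

where p_i, p_j are alt-allele frequencies and p_ij the frequency of the
alt/alt haplotype.  A tagSNP's LD block is every panel site within a window
centered on the tag whose r^2 with the tag reaches the threshold; the tag
itself is always a member with r^2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GeneAnnotation, HaplotypePanel, LDBlock, Variant, nearest_tss_distance

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_R2_MIN = 0.8


def compute_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """r^2 between sites i and j of a phased panel; symmetric, clipped to [0, 1].

    Raises on monomorphic sites, where LD is undefined.
    """
    xi = panel.matrix[i].astype(np.int64)
    xj = panel.matrix[j].astype(np.int64)
    n = xi.size
    n_i = int(xi.sum())
    n_j = int(xj.sum())
    if n_i in (0, n) or n_j in (0, n):
        raise ValueError(
            f"undefined LD: monomorphic site ({panel.sites[i].rsid}, {panel.sites[j].rsid})"
        )
    n_ij = int((xi * xj).sum())
    # integer arithmetic keeps perfect LD at exactly 1.0
    num = (n * n_ij - n_i * n_j) ** 2
    den = n_i * (n - n_i) * n_j * (n - n_j)
    return float(min(num / den, 1.0))


def expand_tag(
    panel: HaplotypePanel,
    tag: Variant,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_min: float = DEFAULT_R2_MIN,
    tss: Optional[Sequence[GeneAnnotation]] = None,
) -> LDBlock:
    """Expand one tagSNP into its LD block.

    Members are all panel sites on the tag's chromosome within
    +/- window_bp/2 of the tag position with r^2 >= r2_min; the tag is
    always included with r^2 = 1.  ``window_bp`` is the full window width,
    read as "a window centered on the tag".
    """
    if not (0.0 < r2_min <= 1.0):
        raise ValueError(f"r2_min must be in (0, 1], got {r2_min}")
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    try:
        ti = panel.site_index(tag.rsid)
    except KeyError:
        raise KeyError(f"tagSNP {tag.rsid} absent from panel") from None
    half = window_bp // 2
    idx = panel.sites_in_window(tag.chrom, tag.pos - half, tag.pos + half)
    # vectorized r^2 of every in-window site against the tag (same counting
    # formula as compute_r2, which remains the scalar reference)
    sub = panel.matrix[idx].astype(np.int64)
    tag_col = panel.matrix[ti].astype(np.int64)
    n = panel.n_haplotypes
    n_s = sub.sum(axis=1)
    n_t = int(tag_col.sum())
    mono = (n_s == 0) | (n_s == n)
    if n_t in (0, n) or mono.any():
        bad = panel.sites[ti].rsid if n_t in (0, n) else \
            panel.sites[idx[int(np.argmax(mono))]].rsid
        raise ValueError(f"undefined LD: monomorphic site {bad}")
    n_st = sub @ tag_col
    num = (n * n_st - n_s * n_t) ** 2
    den = n_s * (n - n_s) * n_t * (n - n_t)
    r2s = np.minimum(num / den, 1.0)
    members: list[tuple[Variant, float]] = []
    for k, r2 in zip(idx, r2s):
        if k == ti:
            members.append((panel.sites[k], 1.0))
        elif r2 >= r2_min:
            members.append((panel.sites[k], float(r2)))
    members.sort(key=lambda t: (t[0].pos, t[0].rsid))
    tss_dist = None
    if tss is not None:
        tss_dist = nearest_tss_distance(tag.chrom, tag.pos, tss)
    return LDBlock(tag=panel.sites[ti], members=members, tss_distance=tss_dist)


@dataclass
class ExpansionResult:
    """The AVS (one block per tag) plus the flattened unique correlated set."""

    blocks: list[LDBlock]
    unique_variants: list[Variant]
    shared_variants: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.unique_variants)


def expand_all(
    panel: HaplotypePanel,
    tags: Sequence[Variant],
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_min: float = DEFAULT_R2_MIN,
    tss: Optional[Sequence[GeneAnnotation]] = None,
) -> ExpansionResult:
    """Expand every tag; report variants shared between blocks and the union."""
    if not tags:
        raise ValueError("tag list is empty")
    blocks = [expand_tag(panel, t, window_bp=window_bp, r2_min=r2_min, tss=tss)
              for t in tags]
    owners: dict[str, list[str]] = {}
    seen: dict[str, Variant] = {}
    for b in blocks:
        for v, _ in b.members:
            owners.setdefault(v.rsid, []).append(b.tag.rsid)
            seen.setdefault(v.rsid, v)
    shared = {rsid: tags_ for rsid, tags_ in owners.items() if len(tags_) > 1}
    unique = sorted(seen.values(), key=lambda v: (v.chrom, v.pos, v.rsid))
    return ExpansionResult(blocks=blocks, unique_variants=unique, shared_variants=shared)
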