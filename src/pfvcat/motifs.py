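"""Allele-specific PWM scanning: how a variant changes TF binding affinity.

A window of sequence is scored against a PWM as a sum of per-position
log2 odds, log2(P_pwm(base) / P_background(base)), with pseudocounts
already folded into the PWM at load time.  For a variant we score the
reference-allele and alternate-allele context sequences independently,
each maximized over every placement of the motif across the variant
position and over both strands; the difference alt - ref quantifies the
allele's effect on binding.  Independent per-allele maximization follows
the convention of allele-disruption scanners such as motifbreakR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BASE_INDEX, PWM, Variant

COMPLEMENT = str.maketrans("ACGT", "TGCA")
DEFAULT_STRONG_THRESHOLD = 1.0


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantContext:
    """Sequence context of length 2k+1 centered on the variant."""

    variant: Variant
    ref_seq: str
    alt_seq: str

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq) or len(self.ref_seq) % 2 != 1:
            raise ValueError("context sequences must have equal odd length")
        k = len(self.ref_seq) // 2
        if self.ref_seq[k] != self.variant.ref or self.alt_seq[k] != self.variant.alt:
            raise ValueError(
                f"{self.variant.rsid}: center bases must carry ref/alt alleles"
            )
        diff = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diff != [k]:
            raise ValueError(
                f"{self.variant.rsid}: sequences must differ at exactly the center"
            )

    @property
    def half_width(self) -> int:
        return len(self.ref_seq) // 2


@dataclass(frozen=True)
class MotifBreakResult:
    rsid: str
    motif_id: str
    ref_score: float
    alt_score: float
    delta: float
    best_offset: int  # of the alt-allele best placement, relative to the variant
    best_strand: str
    effect: str  # strong | weak | none


def score_window(pwm: PWM, seq: str) -> float:
    """Log2-odds score of one window; |seq| must equal the motif length."""
    if len(seq) != len(pwm):
        raise ValueError(f"sequence length {len(seq)} != motif length {len(pwm)}")
    score = 0.0
    for i, base in enumerate(seq):
        bi = BASE_INDEX.get(base)
        if bi is None:
            raise ValueError(f"ambiguous or invalid base {base!r} at position {i}")
        score += np.log2(pwm.matrix[i, bi] / pwm.background[bi])
    return float(score)


def _placements(pwm: PWM, seq: str, k: int):
    """All (score, offset, strand) placements covering position k.

    Offsets are relative to the variant: offset o places the motif window
    at seq[k+o : k+o+L], so o ranges over [-(L-1), 0].  The minus strand is
    scored by reverse-complementing the window.
    """
    L = len(pwm)
    for o in range(-(L - 1), 1):
        start = k + o
        if start < 0 or start + L > len(seq):
            continue
        window = seq[start:start + L]
        yield score_window(pwm, window), o, "+"
        yield score_window(pwm, revcomp(window)), o, "-"


def best_allele_score(
    pwm: PWM, ctx: VariantContext, allele: str
) -> tuple[float, int, str]:
    """Best placement of the motif across the variant for one allele.

    Maximizes over every offset covering the variant position and over both
    strands.  Ties break to the lower offset, then the + strand.
    """
    if allele not in ("ref", "alt"):
        raise ValueError(f"allele must be 'ref' or 'alt', got {allele!r}")
    if ctx.half_width < len(pwm) - 1:
        raise ValueError(
            f"context half-width {ctx.half_width} too short for motif length {len(pwm)}"
        )
    seq = ctx.ref_seq if allele == "ref" else ctx.alt_seq
    k = ctx.half_width
    best: tuple[float, int, str] | None = None
    for score, o, strand in _placements(pwm, seq, k):
        if best is None or score > best[0]:
            best = (score, o, strand)
    assert best is not None
    return best


def motif_break(
    pwm: PWM,
    ctx: VariantContext,
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
) -> MotifBreakResult:
    """Allele-specific disruption result for one motif at one variant.

    ``effect`` is "strong" when |delta| >= strong_threshold and the better
    allele scores above background (max score > 0); "weak" when
    0 < |delta| < strong_threshold under the same positivity condition;
    "none" otherwise.
    """
    ref_score, _, _ = best_allele_score(pwm, ctx, "ref")
    alt_score, alt_off, alt_strand = best_allele_score(pwm, ctx, "alt")
    delta = alt_score - ref_score
    if max(ref_score, alt_score) > 0 and abs(delta) >= strong_threshold:
        effect = "strong"
    elif max(ref_score, alt_score) > 0 and abs(delta) > 0:
        effect = "weak"
    else:
        effect = "none"
    return MotifBreakResult(
        rsid=ctx.variant.rsid,
        motif_id=pwm.motif_id,
        ref_score=ref_score,
        alt_score=alt_score,
        delta=float(delta),
        best_offset=alt_off,
        best_strand=alt_strand,
        effect=effect,
    )


def scan_catalog(
    pwms: Sequence[PWM],
    contexts: Sequence[VariantContext],
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
    min_effect: str = "weak",
) -> dict[str, list[MotifBreakResult]]:
    """motif_break of every PWM against every context; keyed by rsid.

    ``min_effect`` filters the reported hits: "none" keeps everything,
    "weak" drops no-effect results, "strong" keeps only strong ones.
    """
    keep = {"none": ("none", "weak", "strong"),
            "weak": ("weak", "strong"),
            "strong": ("strong",)}[min_effect]
    out: dict[str, list[MotifBreakResult]] = {}
    for ctx in contexts:
        hits = []
        for pwm in pwms:
            res = motif_break(pwm, ctx, strong_threshold)
            if res.effect in keep:
                hits.append(res)
        out[ctx.variant.rsid] = hits
    return out
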