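"""Overlap of the PFV set with a known-causal-variant list.

The comparison is a pooled two-proportion z test between the PFV arm and
the background arm (correlated SNPs that are not PFVs), plus a permutation
version that shuffles the causal labels over the union of both arms and
recomputes the proportion difference.  The permutation test is reported
alongside because a z statistic and its normal-tail p-value can disagree
when sample sizes are small or proportions extreme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass
class OverlapTestResult:
    n_pfv: int
    k_pfv: int
    n_bg: int
    k_bg: int
    z: float
    p: float


def overlap_counts(
    pfv_ids: Iterable[str], bg_ids: Iterable[str], causal_ids: Iterable[str]
) -> tuple[int, int]:
    """Exact set-intersection counts of each arm with the causal list."""
    pfv, bg, causal = set(pfv_ids), set(bg_ids), set(causal_ids)
    if pfv & bg:
        raise ValueError(f"PFV and background arms overlap: {sorted(pfv & bg)[:5]} ...")
    return len(pfv & causal), len(bg & causal)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z statistic and two-sided normal p.

    z = (k1/n1 - k2/n2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with the
    pooled phat = (k1 + k2)/(n1 + n2).  Degenerate pooled variance (all
    successes or all failures) returns z = 0, p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    phat = (k1 + k2) / (n1 + n2)
    var = phat * (1 - phat) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (k1 / n1 - k2 / n2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def overlap_test(
    pfv_ids: Iterable[str], bg_ids: Iterable[str], causal_ids: Iterable[str]
) -> OverlapTestResult:
    pfv, bg = set(pfv_ids), set(bg_ids)
    k1, k2 = overlap_counts(pfv, bg, causal_ids)
    z, p = two_proportion_z(k1, len(pfv), k2, len(bg))
    return OverlapTestResult(n_pfv=len(pfv), k_pfv=k1, n_bg=len(bg), k_bg=k2, z=z, p=p)


def permutation_overlap_test(
    k1: int, n1: int, k2: int, n2: int, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p for the proportion difference.

    Shuffles the k1 + k2 causal labels over the n1 + n2 pooled ids and
    counts permutations with |difference| >= observed, with add-one
    smoothing.
    """
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    rng = np.random.default_rng(seed)
    obs = abs(k1 / n1 - k2 / n2)
    total_k = k1 + k2
    # hypergeometric draw of arm-1 successes under label exchange
    draws = rng.hypergeometric(total_k, n1 + n2 - total_k, n1, size=n_perm)
    diffs = np.abs(draws / n1 - (total_k - draws) / n2)
    extreme = int((diffs >= obs - 1e-12).sum())
    return float((1 + extreme) / (1 + n_perm))
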