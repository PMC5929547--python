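"""Repeated-run simulation studies: type-I calibration and power.

These drive the package's own validation: with no planted signal the
enrichment p-value should be (approximately) uniform across seeded
synthetic datasets; with planted signal it should reject; the estimated
fold should grow with the planted fraction; and the two-proportion z test
should be calibrated under equal overlap fractions.

Study designs are desk-scale but chosen so the checks are meaningful:
the null-calibration design uses 60 AVS blocks with a 10x decoy pool —
enough blocks that the integer block score has wide support (ties make
the add-one empirical p conservative), and enough matched candidates per
block that the replicate null spread tracks the marginal spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .assoc import overlap_counts, two_proportion_z
from .enrichment import EnrichmentResult, build_mrvs, build_null_pool, enrichment_test
from .ld import expand_all
from .simulate import SimConfig, simulate_causal_list, simulate_panel, simulate_tracks, simulate_tss


@dataclass
class EnrichmentStudyConfig:
    """One seeded synthetic enrichment run."""

    n_blocks: int = 60
    decoy_mult: int = 10
    n_haplotypes: int = 200
    snps_per_block: int = 6
    target_r2: float = 0.95
    peak_rate_bg: float = 0.145
    planted_block_fraction: float = 0.0
    n_mrvs: int = 150
    n_tracks_family: int = 1


def enrichment_run(seed: int, study: Optional[EnrichmentStudyConfig] = None) -> EnrichmentResult:
    """Simulate a panel + track under ``study`` conditions and test enrichment."""
    st = study or EnrichmentStudyConfig()
    cfg = SimConfig(
        seed=seed,
        n_blocks=st.n_blocks,
        n_decoy_blocks=st.decoy_mult * st.n_blocks,
        n_haplotypes=st.n_haplotypes,
        snps_per_block=st.snps_per_block,
        target_r2=st.target_r2,
        peak_rate_bg=st.peak_rate_bg,
        planted_block_fraction=st.planted_block_fraction,
    )
    sim = simulate_panel(cfg)
    tss = simulate_tss(cfg, sim.blocks)
    expansion = expand_all(sim.panel, sim.tags, tss=tss)
    pool = build_null_pool(sim.panel, tss, expansion.blocks)
    mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=st.n_mrvs, seed=seed + 1)
    track, _ = simulate_tracks(cfg, sim.avs_blocks)
    return enrichment_test(expansion.blocks, mrvs, track,
                           n_tracks_family=st.n_tracks_family)


def null_calibration_pvalues(n_runs: int = 200, base_seed: int = 0) -> list[float]:
    """Empirical enrichment p across seeded runs with no planted signal."""
    st = EnrichmentStudyConfig(planted_block_fraction=0.0)
    return [enrichment_run(base_seed + i, st).p_empirical for i in range(n_runs)]


@dataclass
class PowerStudyConfig:
    """Planted-signal recovery conditions: modest AVS, low background."""

    n_blocks: int = 20
    decoy_mult: int = 10
    n_haplotypes: int = 200
    snps_per_block: int = 6
    target_r2: float = 0.95
    peak_rate_bg: float = 0.01
    planted_block_fraction: float = 0.5
    n_mrvs: int = 150
    n_tracks_family: int = 5


def power_study(n_runs: int = 100, base_seed: int = 0,
                study: Optional[PowerStudyConfig] = None) -> list[EnrichmentResult]:
    st = study or PowerStudyConfig()
    est = EnrichmentStudyConfig(
        n_blocks=st.n_blocks, decoy_mult=st.decoy_mult,
        n_haplotypes=st.n_haplotypes, snps_per_block=st.snps_per_block,
        target_r2=st.target_r2, peak_rate_bg=st.peak_rate_bg,
        planted_block_fraction=st.planted_block_fraction,
        n_mrvs=st.n_mrvs, n_tracks_family=st.n_tracks_family,
    )
    return [enrichment_run(base_seed + i, est) for i in range(n_runs)]


def fold_by_planted_fraction(
    fractions=(0.0, 0.25, 0.5, 1.0), n_runs: int = 20, base_seed: int = 0,
    n_blocks: int = 20, peak_rate_bg: float = 0.05,
) -> dict[float, float]:
    """Mean enrichment fold at each planted fraction (same seeds per level)."""
    out = {}
    for frac in fractions:
        st = EnrichmentStudyConfig(
            n_blocks=n_blocks, peak_rate_bg=peak_rate_bg,
            planted_block_fraction=frac,
        )
        folds = [enrichment_run(base_seed + i, st).fold for i in range(n_runs)]
        out[float(frac)] = float(np.mean(folds))
    return out


def z_calibration_pvalues(
    n_runs: int = 600, base_seed: int = 0, n_per_arm: int = 800, frac: float = 0.2
) -> list[float]:
    """Two-proportion p under equal overlap fractions with sampling noise.

    Uses the stochastic causal-list mode (per-id Bernoulli inclusion) so the
    counts vary across seeds; with deterministic rounded counts the test
    statistic would be constant.
    """
    pfv_ids = [f"p{i}" for i in range(n_per_arm)]
    bg_ids = [f"b{i}" for i in range(n_per_arm)]
    ps = []
    for i in range(n_runs):
        causal = simulate_causal_list(pfv_ids, bg_ids, frac, frac,
                                      seed=base_seed + i, stochastic=True)
        k1, k2 = overlap_counts(pfv_ids, bg_ids, causal)
        _, p = two_proportion_z(k1, n_per_arm, k2, n_per_arm)
        ps.append(p)
    return ps
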