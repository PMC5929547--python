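"""Matched-null variant-set enrichment: scores, pools, MRVS, p-values."""

import numpy as np
import pytest

from pfvcat import (
    FeatureTrack,
    GenomicInterval,
    SimConfig,
    build_mrvs,
    build_null_pool,
    enrichment_score,
    enrichment_test,
    expand_all,
    simulate_panel,
)
from pfvcat.enrichment import match_candidates
from pfvcat.simulate import simulate_tracks, simulate_tss


@pytest.fixture(scope="module")
def setup():
    cfg = SimConfig(n_blocks=6, n_decoy_blocks=30, n_haplotypes=200,
                    snps_per_block=6, target_r2=0.95,
                    peak_rate_bg=0.1, planted_block_fraction=0.5, seed=23)
    sim = simulate_panel(cfg)
    tss = simulate_tss(cfg, sim.blocks)
    expansion = expand_all(sim.panel, sim.tags, tss=tss)
    pool = build_null_pool(sim.panel, tss, expansion.blocks)
    return cfg, sim, tss, expansion, pool


def brute_force_score(blocks, track):
    """O(n_variants * n_peaks) double loop over every (variant, peak) pair."""
    score = 0
    peaks = list(track.intervals())
    for b in blocks:
        hit = False
        for v in b.variants:
            for iv in peaks:
                if iv.chrom == v.chrom and iv.start < v.pos <= iv.end:
                    hit = True
        if hit:
            score += 1
    return score


class TestEnrichmentScore:
    def test_empty_track_scores_zero(self, setup):
        _, _, _, expansion, _ = setup
        assert enrichment_score(expansion.blocks, FeatureTrack("empty")) == 0

    def test_fully_planted_track_scores_all_blocks(self):
        cfg = SimConfig(n_blocks=8, n_decoy_blocks=0, n_haplotypes=60,
                        peak_rate_bg=0.0, planted_block_fraction=1.0, seed=2)
        sim = simulate_panel(cfg)
        track, _ = simulate_tracks(cfg, sim.avs_blocks)
        expansion = expand_all(sim.panel, sim.tags)
        assert enrichment_score(expansion.blocks, track) == 8

    def test_matches_brute_force_double_loop(self, setup, rng):
        _, sim, _, expansion, _ = setup
        for trial in range(5):
            track = FeatureTrack("rand")
            for i in range(50):
                s = int(rng.integers(1_000_000, 16_000_000))
                track.add(GenomicInterval("chrS", s, s + int(rng.integers(100, 2000))))
            assert enrichment_score(expansion.blocks, track) == \
                   brute_force_score(expansion.blocks, track)


class TestBuildNullPool:
    def test_avs_only_panel_exhausts_pool(self):
        cfg = SimConfig(n_blocks=3, n_decoy_blocks=0, n_haplotypes=80,
                        snps_per_block=6, target_r2=1.0, seed=31)
        sim = simulate_panel(cfg)
        expansion = expand_all(sim.panel, sim.tags)
        with pytest.raises(ValueError, match="insufficient null pool"):
            build_null_pool(sim.panel, [], expansion.blocks)

    def test_perfect_decoy_blocks_collapse_to_one_entry_each(self):
        cfg = SimConfig(n_blocks=2, n_decoy_blocks=20, n_haplotypes=80,
                        snps_per_block=6, target_r2=1.0, seed=32)
        sim = simulate_panel(cfg)
        tss = simulate_tss(cfg, sim.blocks)
        expansion = expand_all(sim.panel, sim.tags, tss=tss)
        pool = build_null_pool(sim.panel, tss, expansion.blocks)
        assert len(pool) == 20

    def test_pool_disjoint_from_avs(self, setup):
        _, _, _, expansion, pool = setup
        avs_rsids = set().union(*(b.member_rsids for b in expansion.blocks))
        for c in pool:
            assert not (c.member_rsids & avs_rsids)


class TestBuildMrvs:
    def test_replicates_satisfy_matching_invariants(self, setup):
        _, _, _, expansion, pool = setup
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=50, seed=7)
        avs_rsids = set().union(*(b.member_rsids for b in expansion.blocks))
        cands = match_candidates(expansion.blocks, pool)
        for rep in mrvs:
            assert len(rep) == len(expansion.blocks)
            chosen_ids = [id(b) for b in rep]
            assert len(set(chosen_ids)) == len(rep)  # without replacement within
            for avs_block, null_block in zip(expansion.blocks, rep):
                assert abs(null_block.tag_maf - avs_block.tag_maf) <= 0.02
                assert abs(null_block.size - avs_block.size) <= \
                       max(1, round(0.1 * avs_block.size))
                assert not (null_block.member_rsids & avs_rsids)
        # every selected block is a declared candidate
        pool_index = {id(b): j for j, b in enumerate(pool)}
        for rep in mrvs:
            for k, b in enumerate(rep):
                assert pool_index[id(b)] in cands[k]

    def test_deterministic_under_seed(self, setup):
        _, _, _, expansion, pool = setup
        a = build_mrvs(expansion.blocks, pool, n_mrvs=20, seed=5)
        b = build_mrvs(expansion.blocks, pool, n_mrvs=20, seed=5)
        assert [[blk.tag.rsid for blk in rep] for rep in a] == \
               [[blk.tag.rsid for blk in rep] for rep in b]

    def test_zero_tolerances_starve_matching(self, setup):
        _, _, _, expansion, pool = setup
        with pytest.raises(ValueError, match="no matching pool candidates"):
            build_mrvs(expansion.blocks, pool, n_mrvs=5,
                       maf_tol=0.0, tss_log10_tol=0.0, size_tol=0, seed=1)

    def test_single_candidate_forces_identical_replicates(self):
        cfg = SimConfig(n_blocks=1, n_decoy_blocks=1, n_haplotypes=80,
                        snps_per_block=6, target_r2=1.0, seed=41)
        sim = simulate_panel(cfg)
        tss = simulate_tss(cfg, sim.blocks)
        expansion = expand_all(sim.panel, sim.tags, tss=tss)
        pool = build_null_pool(sim.panel, tss, expansion.blocks)
        assert len(pool) == 1
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=30, seed=1)
        first = [b.tag.rsid for b in mrvs[0]]
        assert all([b.tag.rsid for b in rep] == first for rep in mrvs)


class TestEnrichmentTest:
    def test_planted_signal_attains_minimum_p(self):
        cfg = SimConfig(n_blocks=10, n_decoy_blocks=100, n_haplotypes=200,
                        snps_per_block=6, target_r2=0.95,
                        peak_rate_bg=0.0, planted_block_fraction=1.0, seed=51)
        sim = simulate_panel(cfg)
        tss = simulate_tss(cfg, sim.blocks)
        expansion = expand_all(sim.panel, sim.tags, tss=tss)
        pool = build_null_pool(sim.panel, tss, expansion.blocks)
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=100, seed=2)
        track, _ = simulate_tracks(cfg, sim.avs_blocks)
        res = enrichment_test(expansion.blocks, mrvs, track)
        # planted peaks cover only AVS blocks: no null replicate can match
        assert res.observed == 10
        assert all(s == 0 for s in res.null_scores)
        assert res.p_empirical == pytest.approx(1 / 101)
        assert res.fold == pytest.approx(10 / 0.5)

    def test_null_equal_to_observed_gives_p_one(self, setup):
        _, sim, _, expansion, pool = setup
        cfg = setup[0]
        # a track covering every variant everywhere: all scores maximal
        track = FeatureTrack("everything",
                             [GenomicInterval("chrS", 0, 300_000_000)])
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=40, seed=3)
        res = enrichment_test(expansion.blocks, mrvs, track)
        assert res.observed == len(expansion.blocks)
        assert res.p_empirical == 1.0
        assert res.fold == pytest.approx(1.0)

    def test_bonferroni_arithmetic(self, setup):
        _, _, _, expansion, pool = setup
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=40, seed=3)
        track = FeatureTrack("empty")
        res = enrichment_test(expansion.blocks, mrvs, track, n_tracks_family=5)
        assert res.p_adjusted == min(1.0, res.p_empirical * 5)

    def test_add_one_p_never_zero(self, setup):
        _, _, _, expansion, pool = setup
        mrvs = build_mrvs(expansion.blocks, pool, n_mrvs=25, seed=9)
        for track in (FeatureTrack("empty"),
                      FeatureTrack("all", [GenomicInterval("chrS", 0, 3 * 10**8)])):
            res = enrichment_test(expansion.blocks, mrvs, track)
            assert res.p_empirical >= 1 / 26
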