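"""Pairwise block alignment, conservation profiles, footprints, empirical FDR."""

import numpy as np
import pytest

from pbmgrn.footprint import (
    AlignedBlock,
    AlignScoring,
    ConservationProfile,
    Footprint,
    PairwiseAlignment,
    aggregate_profile,
    align_promoter_pair,
    conservation_profile,
    conserved_instances,
    empirical_fdr,
    extract_footprints,
    gene_level_fdr,
)
from pbmgrn.promoters import MotifHit
from pbmgrn.simulate import GroundTruth, SimulationConfig, background_pool, simulate_orthologs
from tests.conftest import random_dna


class TestAlign:
    def test_identical_sequences_single_full_block(self, rng):
        q = random_dna(rng, 100)
        aln = align_promoter_pair(q, q)
        assert len(aln.blocks) == 1
        b = aln.blocks[0]
        assert (b.query_start, b.query_end) == (0, 100)
        assert b.identity == pytest.approx(1.0)

    def test_unrelated_sequences_mostly_empty(self):
        empty = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            a = random_dna(r, 300)
            b = random_dna(r, 300)
            if not align_promoter_pair(a, b).blocks:
                empty += 1
        assert empty >= 45  # >= 90% of seeds

    def test_planted_exact_insert_found_at_interval(self, rng):
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)
        b = b[:100] + a[50:80] + b[130:]
        aln = align_promoter_pair(a, b)
        # one block must cover the planted interval at the planted shift
        # (chance matches at the boundary may extend it slightly)
        assert any(
            blk.query_start <= 50 and blk.query_end >= 80
            and blk.ortho_start - blk.query_start == 50
            for blk in aln.blocks
        )

    def test_blocks_non_overlapping_on_both_sequences(self, rng):
        a = random_dna(rng, 200)
        b = a[:80] + random_dna(rng, 40) + a[120:]
        aln = align_promoter_pair(a, b)
        qcov = set()
        ocov = set()
        for blk in aln.blocks:
            qr = set(range(blk.query_start, blk.query_end))
            orr = set(range(blk.ortho_start, blk.ortho_end))
            assert not qr & qcov
            assert not orr & ocov
            qcov |= qr
            ocov |= orr

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            align_promoter_pair("", "ACGT")


class TestProfile:
    def test_no_alignments_zero_profile(self):
        prof = aggregate_profile("g", 50, [])
        assert prof.support.sum() == 0

    def test_two_species_same_interval(self):
        blocks = [AlignedBlock(10, 20, 0, 10, 1.0)]
        alns = [
            PairwiseAlignment("g", "sp1", list(blocks)),
            PairwiseAlignment("g", "sp2", list(blocks)),
        ]
        prof = aggregate_profile("g", 30, alns)
        assert (prof.support[10:20] == 2).all()
        assert prof.support[:10].sum() == 0 and prof.support[20:].sum() == 0

    def test_species_contributes_once_despite_two_blocks(self):
        alns = [
            PairwiseAlignment("g", "sp1",
                              [AlignedBlock(5, 15, 0, 10, 1.0),
                               AlignedBlock(10, 20, 30, 40, 1.0)])
        ]
        prof = aggregate_profile("g", 25, alns)
        assert prof.support.max() == 1

    def test_random_blocks_per_position_recount(self, rng):
        n = 60
        alns = []
        for sp in range(4):
            blocks = []
            used = 0
            while used < n - 12 and rng.random() < 0.8:
                start = used + int(rng.integers(0, 5))
                end = min(n, start + int(rng.integers(8, 15)))
                if end <= start:
                    break
                blocks.append(AlignedBlock(start, end, start, end, 1.0))
                used = end + 1
            alns.append(PairwiseAlignment("g", f"sp{sp}", blocks))
        prof = aggregate_profile("g", n, alns)
        for pos in range(n):
            count = sum(
                1 for aln in alns
                if any(b.query_start <= pos < b.query_end for b in aln.blocks)
            )
            assert prof.support[pos] == count

    def test_block_outside_bounds_error(self):
        alns = [PairwiseAlignment("g", "sp1", [AlignedBlock(45, 55, 0, 10, 1.0)])]
        with pytest.raises(ValueError):
            aggregate_profile("g", 50, alns)

    def test_profile_mass_conservation(self, rng):
        q = random_dna(rng, 200)
        group_seqs = {f"sp{i}": q for i in range(3)}
        from pbmgrn.footprint import OrthologGroup

        group = OrthologGroup("g", group_seqs)
        alns = [
            align_promoter_pair(q, s, query_id="g", species=sp)
            for sp, s in group.promoters.items()
        ]
        prof = aggregate_profile("g", 200, alns)
        per_species = sum(
            sum(b.query_end - b.query_start for b in a.blocks) for a in alns
        )
        assert prof.support.sum() == per_species


class TestFootprints:
    def test_constant_support_single_footprint(self):
        prof = ConservationProfile("g", np.full(30, 3))
        fps = extract_footprints(prof, 3)
        assert len(fps) == 1
        assert (fps[0].start, fps[0].end) == (0, 30)

    def test_run_extraction_example(self):
        prof = ConservationProfile("g", np.array([0, 2, 2, 0, 2]))
        fps = extract_footprints(prof, 2)
        assert [(f.start, f.end) for f in fps] == [(1, 3), (4, 5)]
        assert [f.length for f in fps] == [2, 1]

    def test_random_profiles_match_naive_scan(self, rng):
        for _ in range(20):
            support = rng.integers(0, 4, size=40)
            prof = ConservationProfile("g", support)
            c = int(rng.integers(1, 4))
            fps = {(f.start, f.end) for f in extract_footprints(prof, c)}
            naive = set()
            i = 0
            while i < 40:
                if support[i] >= c:
                    j = i
                    while j < 40 and support[j] >= c:
                        j += 1
                    naive.add((i, j))
                    i = j
                else:
                    i += 1
            assert fps == naive

    def test_higher_level_nested_in_lower(self, rng):
        support = rng.integers(0, 5, size=60)
        prof = ConservationProfile("g", support)
        for c in range(1, 4):
            lower = extract_footprints(prof, c)
            higher = extract_footprints(prof, c + 1)
            for hi in higher:
                assert any(lo.start <= hi.start and hi.end <= lo.end for lo in lower)


class TestEmpiricalFDR:
    def _planted_setup(self, seed, n_genes=25, length=300):
        cfg = SimulationConfig(n_species=3, conserved_window=40)
        truth = GroundTruth()
        truth.planted_sites = {"gene0": (120, "+", "ATTGCGTA", "TF_A")}
        rng = np.random.default_rng(seed)
        proms = {f"gene{i}": random_dna(rng, length) for i in range(n_genes)}
        groups = simulate_orthologs(cfg, rng, proms, truth)
        return truth, proms, groups

    def test_no_footprints_vacuous(self, rng):
        truth, proms, groups = self._planted_setup(0)
        pool = background_pool(groups, "gene1")
        assert empirical_fdr("gene1", proms["gene1"], groups["gene1"], [], pool) == []

    def test_planted_window_low_fdr(self):
        truth, proms, groups = self._planted_setup(1)
        prof = conservation_profile("gene0", proms["gene0"], groups["gene0"])
        fps = extract_footprints(prof, 3)
        assert fps
        pool = background_pool(groups, "gene0")
        scored = empirical_fdr("gene0", proms["gene0"], groups["gene0"], fps, pool,
                               n_samples=100, seed=7)
        assert min(f.fdr for f in scored) < 0.05
        assert gene_level_fdr(scored) == min(f.fdr for f in scored)

    def test_determinism_under_fixed_seed(self):
        truth, proms, groups = self._planted_setup(2)
        prof = conservation_profile("gene0", proms["gene0"], groups["gene0"])
        fps = extract_footprints(prof, 2)
        pool = background_pool(groups, "gene0")
        a = empirical_fdr("gene0", proms["gene0"], groups["gene0"], fps, pool,
                          n_samples=50, seed=11)
        b = empirical_fdr("gene0", proms["gene0"], groups["gene0"], fps, pool,
                          n_samples=50, seed=11)
        assert [f.fdr for f in a] == [f.fdr for f in b]

    def test_fdr_non_increasing_in_support_level(self):
        truth, proms, groups = self._planted_setup(3)
        prof = conservation_profile("gene0", proms["gene0"], groups["gene0"])
        ws, we = truth.conserved_windows["gene0"]
        # same interval scored at each level against the same nulls
        fps = [Footprint("gene0", ws, we, level) for level in (1, 2, 3)]
        pool = background_pool(groups, "gene0")
        scored = empirical_fdr("gene0", proms["gene0"], groups["gene0"], fps, pool,
                               n_samples=50, seed=13)
        fdrs = [f.fdr for f in sorted(scored, key=lambda f: f.level)]
        assert fdrs == sorted(fdrs, reverse=True)

    def test_insufficient_pool_error(self):
        truth, proms, groups = self._planted_setup(4, n_genes=2)
        with pytest.raises(ValueError, match="sp1"):
            empirical_fdr("gene0", proms["gene0"], groups["gene0"],
                          [Footprint("gene0", 0, 10, 1)], {"sp1": []})


class TestConservedInstances:
    def test_hit_inside_significant_footprint(self):
        hits = [MotifHit("g", "AAAAAAAA", 12, "+")]
        fps = [Footprint("g", 10, 25, 3, fdr=0.01)]
        assert conserved_instances(hits, fps)[0].conserved

    def test_hit_straddling_edge_not_conserved(self):
        hits = [MotifHit("g", "AAAAAAAA", 20, "+")]  # covers [20, 28)
        fps = [Footprint("g", 10, 25, 3, fdr=0.01)]
        assert not conserved_instances(hits, fps)[0].conserved

    def test_insignificant_footprint_ignored(self):
        hits = [MotifHit("g", "AAAAAAAA", 12, "+")]
        fps = [Footprint("g", 10, 25, 3, fdr=0.20)]
        assert not conserved_instances(hits, fps)[0].conserved

    def test_random_sets_match_interval_oracle(self, rng):
        for _ in range(20):
            hits = [
                MotifHit("g", "AAAAAAAA", int(rng.integers(0, 90)), "+")
                for _ in range(8)
            ]
            fps = [
                Footprint("g", s, s + int(rng.integers(4, 20)), 1,
                          fdr=float(rng.uniform(0, 0.1)))
                for s in rng.integers(0, 90, size=5)
            ]
            out = conserved_instances(hits, fps)
            for h, o in zip(hits, out):
                want = any(
                    f.fdr < 0.05 and f.start <= h.offset and h.offset + 8 <= f.end
                    for f in fps
                )
                assert o.conserved == want
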