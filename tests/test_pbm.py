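"""Probe normalization, enrichment scoring, core words and PWMs."""

import numpy as np
import pytest

from pbmgrn.patterns import KmerPattern, canonical, find_matches, revcomp
from pbmgrn.pbm import (
    build_pwm,
    compute_enrichment_table,
    enrichment_score,
    normalize_probes,
    select_core_words,
    significant_patterns,
    top_pattern,
)
from tests.conftest import make_experiment, make_table, random_dna


def brute_force_es(intensities, fg_idx):
    """Explicit pairwise U-statistic (ties count one half)."""
    fg = set(fg_idx)
    u = 0.0
    nf = nb = 0
    for i, vi in enumerate(intensities):
        if i not in fg:
            continue
        nf += 1
        for j, vj in enumerate(intensities):
            if j in fg:
                continue
            u += 1.0 if vi > vj else (0.5 if vi == vj else 0.0)
    nb = len(intensities) - nf
    return u / (nf * nb) - 0.5


class TestNormalize:
    def test_constant_input_scale_invariance(self):
        exp = make_experiment(["ACGT" * 3] * 5, [7.0] * 5)
        out = normalize_probes([exp])
        assert len({p.intensity for p in out.probes}) == 1

    def test_identical_replicates_equal_single(self):
        seqs = ["ACGTACGTACGT", "TTTTACGTCCCC", "GGGGTTTTAAAA"]
        vals = [5.0, 10.0, 20.0]
        single = normalize_probes([make_experiment(seqs, vals)])
        double = normalize_probes(
            [make_experiment(seqs, vals, replicate=1), make_experiment(seqs, vals, replicate=2)]
        )
        for a, b in zip(single.probes, double.probes):
            assert a.intensity == pytest.approx(b.intensity, rel=1e-12)

    def test_scaled_replicate_preserves_rank_order(self, rng):
        seqs = [random_dna(rng, 10) for _ in range(20)]
        vals = list(rng.uniform(1, 100, size=20))
        reps = [
            make_experiment(seqs, vals, replicate=1),
            make_experiment(seqs, [2 * v for v in vals], replicate=2),
        ]
        out = normalize_probes(reps)
        got_order = np.argsort([p.intensity for p in out.probes])
        want_order = np.argsort(vals)  # direct sort oracle on replicate 1
        assert list(got_order) == list(want_order)

    def test_mismatched_probe_ids_error(self):
        a = make_experiment(["ACGT"], [1.0])
        b = make_experiment(["ACGT"], [1.0])
        object.__setattr__(b.probes[0], "probe_id", "other")
        with pytest.raises(ValueError, match="other"):
            normalize_probes([a, b])

    def test_empty_probe_list_error(self):
        with pytest.raises(ValueError):
            make_experiment([], [])

    def test_low_probes_flagged_not_dropped(self):
        exp = make_experiment(["ACGT"] * 4, [10.0, 10.0, 10.0, 1e-9])
        out = normalize_probes([exp])
        assert len(out.probes) == 4
        assert "p3" in out.flagged_probes


class TestEnrichmentScore:
    def test_maximal_separation(self):
        # foreground = probes containing AAAA, all brighter than background
        seqs = ["AAAACGTC", "CAAAAGTC", "CGTCGTCG", "GTCGCGTC"]
        exp = make_experiment(seqs, [10.0, 9.0, 1.0, 0.5])
        rec = enrichment_score(exp, "AAAA")
        assert rec.es == pytest.approx(0.5, abs=1e-12)

    def test_all_ties_give_zero(self):
        seqs = ["AAAACGTC", "CAAAAGTC", "CGTCGTCG", "GTCGCGTC"]
        exp = make_experiment(seqs, [3.0, 3.0, 3.0, 3.0])
        rec = enrichment_score(exp, "AAAA")
        assert rec.es == pytest.approx(0.0, abs=1e-12)

    def test_six_probe_pair_enumeration(self):
        # foreground = {10, 8, 2}: enumerate all 9 pairs by hand
        seqs = [
            "AAAATTTT",  # 10 fg
            "CCGGCCGG",  # 9
            "TAAAATTT",  # 8  fg
            "CCGGGGCC",  # 3
            "TTAAAATT",  # 2  fg
            "GGCCCCGG",  # 1
        ]
        intens = [10.0, 9.0, 8.0, 3.0, 2.0, 1.0]
        exp = make_experiment(seqs, intens)
        rec = enrichment_score(exp, "AAAA")
        assert rec.es == pytest.approx(brute_force_es(intens, {0, 2, 4}), abs=1e-12)
        # pairs won: 10 beats {9,3,1}; 8 beats {3,1}; 2 beats {1} -> U = 6
        assert rec.es == pytest.approx(6.0 / 9.0 - 0.5, abs=1e-12)

    def test_oracle_equivalence_small_probe_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 31))
            seqs = [random_dna(rng, 12) for _ in range(n)]
            intens = list(np.round(rng.uniform(0, 50, size=n), 1))  # some ties
            exp = make_experiment(seqs, intens)
            pat = canonical(random_dna(rng, 3))
            fg = {i for i, s in enumerate(seqs) if find_matches(s, pat)}
            if not fg or len(fg) == n:
                continue
            rec = enrichment_score(exp, pat)
            assert rec.es == pytest.approx(brute_force_es(intens, fg), abs=1e-12)
            assert -0.5 <= rec.es <= 0.5

    def test_revcomp_pattern_same_score(self, rng):
        seqs = [random_dna(rng, 14) for _ in range(15)]
        exp = make_experiment(seqs, list(rng.uniform(1, 10, size=15)))
        pat = "ACGT"  # try several
        for pat in ("ACG", "TTA", "GCGC"):
            fg = [i for i, s in enumerate(seqs) if find_matches(s, pat)]
            if not fg or len(fg) == len(seqs):
                continue
            a = enrichment_score(exp, KmerPattern.from_text(pat))
            b = enrichment_score(exp, KmerPattern.from_text(revcomp(pat)))
            assert a.es == b.es

    def test_absent_pattern_error(self):
        exp = make_experiment(["ACGTACGT"], [1.0])
        with pytest.raises(ValueError, match="absent"):
            enrichment_score(exp, "TTTT")

    def test_monotone_response_to_foreground_boost(self, rng):
        seqs = [random_dna(rng, 12) for _ in range(20)]
        intens = np.array(rng.uniform(1, 10, size=20))
        pat = "AAA"
        fg = np.array([bool(find_matches(s, pat)) for s in seqs])
        if not fg.any() or fg.all():
            seqs[0] = "AAAGGGTTTCCC"
            fg = np.array([bool(find_matches(s, pat)) for s in seqs])
        base = enrichment_score(make_experiment(seqs, list(intens)), pat).es
        boosted = intens + fg * 100.0  # strictly separates groups
        high = enrichment_score(make_experiment(seqs, list(boosted)), pat).es
        assert high >= base
        assert high == pytest.approx(0.5, abs=1e-12)


class TestTableAndSignificance:
    def test_threshold_inclusive_at_040(self):
        table = make_table({"TF_X": {"AAAA": 0.40, "CCCC": 0.399, "GGCC": 0.41}})
        sig = significant_patterns(table)
        assert sig == {"AAAA", "GGCC"}

    def test_all_below_threshold_empty(self):
        table = make_table({"TF_X": {"AAAA": 0.1, "CCCC": 0.2}})
        assert significant_patterns(table) == set()

    def test_random_table_vs_exhaustive_scan(self, rng):
        pats = sorted({canonical(random_dna(rng, 5)) for _ in range(30)})
        es = {
            tf: {p: float(rng.uniform(-0.5, 0.5)) for p in pats}
            for tf in ("TF_1", "TF_2", "TF_3")
        }
        table = make_table(es)
        want = {
            p for p in pats
            if any(es[tf][p] >= 0.40 for tf in es)
        }
        assert significant_patterns(table) == want

    def test_table_es_matches_single_pattern_scorer(self, rng):
        seqs = [random_dna(rng, 12) for _ in range(25)]
        exp = make_experiment(seqs, list(rng.uniform(1, 10, size=25)))
        table = compute_enrichment_table([exp], k=4, max_gap=0, min_foreground=1)
        for p in list(table.es.index)[:15]:
            rec = enrichment_score(exp, p)
            assert table.es.at[p, "TF_X"] == pytest.approx(rec.es, abs=1e-12)
            assert table.n_foreground.at[p, "TF_X"] == rec.n_foreground

    def test_min_foreground_filters_rare_words(self, rng):
        seqs = [random_dna(rng, 12) for _ in range(25)]
        exp = make_experiment(seqs, list(rng.uniform(1, 10, size=25)))
        table = compute_enrichment_table([exp], k=6, max_gap=0, min_foreground=3)
        nf = table.n_foreground["TF_X"].dropna()
        assert (nf >= 3).all()


class TestCoreWords:
    def test_single_pattern_cover_is_substring(self):
        sig = {canonical("TTGCGTAA")}
        table = make_table({"TF_X": {canonical("TTGCGTAA"): 0.45}})
        cores = select_core_words(table, sig)
        assert len(cores) == 1
        core = cores[0].pattern.text
        host = canonical("TTGCGTAA")
        assert core in host or revcomp(core) in host or "N" in core

    def test_shared_6mer_gives_cover_of_one(self):
        a, b = "ATGCGTAC", "TTGCGTAG"  # share TGCGTA
        sig = {canonical(a), canonical(b)}
        table = make_table({"TF_X": {canonical(a): 0.5, canonical(b): 0.45}})
        cores = select_core_words(table, sig)
        assert len(cores) == 1

    def test_disjoint_patterns_need_one_core_each(self):
        a, b = "AAAAAAAA", "CCCCGGGG"
        sig = {canonical(a), canonical(b)}
        table = make_table({"TF_X": {canonical(a): 0.5, canonical(b): 0.45}})
        cores = select_core_words(table, sig)
        assert len(cores) == 2

    def test_empty_significant_set(self):
        table = make_table({"TF_X": {"AAAA": 0.1}})
        assert select_core_words(table, set()) == []

    def test_core_shapes(self):
        table = make_table({"TF_X": {canonical("ACGTACGT"): 0.5}})
        for cw in select_core_words(table, {canonical("ACGTACGT")}):
            w, g = cw.pattern.width, cw.pattern.gap_len
            assert (w, g) in ((6, 0), (7, 1))


class TestPWM:
    def test_top1_point_mass_on_seed(self):
        word = canonical("ATGCGTAC")
        table = make_table({"TF_X": {word: 0.5}})
        pwm = build_pwm(table, "TF_X", top_n=1)
        assert pwm.consensus() == word
        for i, b in enumerate(word):  # point mass up to the pseudocount
            assert pwm.probs[i]["ACGT".index(b)] > 0.9

    def test_two_identical_words_same_as_one(self):
        word = canonical("ATGCGTAC")
        t1 = make_table({"TF_X": {word: 0.5}})
        p1 = build_pwm(t1, "TF_X", top_n=1)
        p2 = build_pwm(t1, "TF_X", top_n=5)  # only one word available
        assert p1.probs == p2.probs

    def test_missing_tf_error(self):
        table = make_table({"TF_X": {"AAAA": 0.5}})
        with pytest.raises(ValueError):
            build_pwm(table, "TF_Y")

    def test_planted_recovery_consensus_contains_core(self, rng):
        from pbmgrn.simulate import SimulationConfig, simulate_pbm
        from pbmgrn.pbm import normalize_probes

        cfg = SimulationConfig()
        exps, _ = simulate_pbm(cfg, rng)
        norm = normalize_probes(exps["TF_A"])
        table = compute_enrichment_table([norm], k=8, max_gap=0)
        pwm = build_pwm(table, "TF_A", top_n=10)
        cons = pwm.consensus()
        core = "TTGCGT"
        assert core in cons or revcomp(core) in cons
        top = top_pattern(table, "TF_A")
        assert core in top or revcomp(core) in top
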