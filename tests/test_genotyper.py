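"""Reciprocal screening: ASR sets, pool seeding, exclusion, pair scoring,
pool iteration, paralog correction and the quality statistic."""

import numpy as np
import pytest

import oracles
from hlacall import (
    AlleleDatabase,
    AlleleRecord,
    AsrTable,
    GeneCall,
    GenePairScore,
    build_asr_table,
    deduplicate,
    exclude_false_alleles,
    iterate_pool,
    paralog_correction,
    quality_check,
    score_pairs,
    seed_real_pool,
)
from hlacall.genotype import top_pairs

BASES = "ACGT"


def table(read_to_alleles, candidates_by_gene):
    gene_of = {a: g for g, al in candidates_by_gene.items() for a in al}
    return AsrTable(
        read_to_alleles={r: frozenset(s) for r, s in read_to_alleles.items()},
        candidates_by_gene=candidates_by_gene,
        gene_of=gene_of,
    )


def reads_for(allele_sets):
    """{label: (mapping set, count)} -> read_to_alleles dict."""
    out = {}
    for label, (alleles, count) in allele_sets.items():
        for i in range(count):
            out[f"{label}_{i}"] = frozenset(alleles)
    return out


class TestAsrTable:
    def test_identical_alleles_have_empty_asr(self):
        t = table(reads_for({"x": ({"A*01:01", "A*02:01"}, 10)}),
                  {"A": ["A*01:01", "A*02:01"]})
        assert t.asr("A*01:01", "A*02:01") == frozenset()
        assert t.asr("A*02:01", "A*01:01") == frozenset()

    def test_asr_sets_of_a_pair_are_disjoint(self):
        t = table(
            reads_for({"x": ({"A*01:01"}, 3), "y": ({"A*02:01"}, 4),
                       "b": ({"A*01:01", "A*02:01"}, 5)}),
            {"A": ["A*01:01", "A*02:01"]},
        )
        a = t.asr("A*01:01", "A*02:01")
        b = t.asr("A*02:01", "A*01:01")
        assert len(a) == 3 and len(b) == 4 and not (a & b)

    def test_cross_gene_read_not_unique_but_in_pair_asr(self):
        t = table(
            reads_for({"x": ({"A*01:01", "B*01:01"}, 7)}),
            {"A": ["A*01:01", "A*02:01"], "B": ["B*01:01"]},
        )
        assert t.unique_counts["A*01:01"] == 0
        assert len(t.asr("A*01:01", "A*02:01")) == 7

    def test_single_variant_asr_from_mapping(self, cfg):
        # reads only from X; X and Y differ at position 150 of a 300 bp
        # exon.  A read qualifies on Y iff one of the two exact runs around
        # the variant reaches 70 bp, i.e. the variant sits in the first 30
        # or last 30 read bases; the remaining reads are X-specific.
        rng = np.random.default_rng(6)
        x = "".join(rng.choice(list(BASES), size=300))
        y = x[:150] + ("A" if x[150] != "A" else "C") + x[151:]
        db = AlleleDatabase.from_records(
            [AlleleRecord("A*01:01", "A", x, ((0, 300),)),
             AlleleRecord("A*02:01", "A", y, ((0, 300),))]
        )
        reads = [(f"r{s}", x[s : s + 100]) for s in range(0, 201)]
        t = build_asr_table(db, {"A*01:01", "A*02:01"}, deduplicate(reads), cfg)
        expected_specific = {f"r{s}" for s in range(81, 121)}
        assert t.asr("A*01:01", "A*02:01") == frozenset(expected_specific)
        assert t.asr("A*02:01", "A*01:01") == frozenset()

    def test_zero_survivor_gene_is_empty_not_error(self, cfg):
        db = AlleleDatabase.from_records(
            [AlleleRecord("A*01:01", "A", "ACGT" * 30, ((0, 120),))]
        )
        t = build_asr_table(db, set(), deduplicate([]), cfg)
        assert t.candidates_by_gene["A"] == []


class TestRealPool:
    @pytest.mark.parametrize("n_unique,expected", [(6, True), (5, False)])
    def test_pool_membership_boundary(self, cfg, n_unique, expected):
        t = table(reads_for({"u": ({"A*01:01"}, n_unique)}),
                  {"A": ["A*01:01"]})
        assert ("A*01:01" in seed_real_pool(t, cfg)) is expected


class TestExclusion:
    def make(self, ca, cb):
        return table(
            reads_for({"a": ({"A*01:01"}, ca), "b": ({"A*02:01"}, cb)}),
            {"A": ["A*01:01", "A*02:01"]},
        )

    def test_15_fold_boundary_excludes(self, cfg):
        kept = exclude_false_alleles(self.make(30, 2), cfg)
        assert kept["A"] == ["A*01:01"]

    def test_just_below_15_fold_retains_both(self, cfg):
        kept = exclude_false_alleles(self.make(29, 2), cfg)
        assert kept["A"] == ["A*01:01", "A*02:01"]

    def test_zero_vs_nonzero_excludes(self, cfg):
        kept = exclude_false_alleles(self.make(1, 0), cfg)
        assert kept["A"] == ["A*01:01"]

    def test_zero_vs_zero_keeps_both(self, cfg):
        t = table(reads_for({"x": ({"A*01:01", "A*02:01"}, 5)}),
                  {"A": ["A*01:01", "A*02:01"]})
        assert exclude_false_alleles(t, cfg)["A"] == ["A*01:01", "A*02:01"]

    def test_simultaneous_no_cascade(self, cfg):
        # c excluded by a; b excluded by a; decisions use the pre-exclusion
        # table, so removing c must not rescue b
        t = table(
            reads_for({"a": ({"A*01:01"}, 60), "b": ({"A*02:01"}, 2),
                       "c": ({"A*03:01"}, 1)}),
            {"A": ["A*01:01", "A*02:01", "A*03:01"]},
        )
        assert exclude_false_alleles(t, cfg)["A"] == ["A*01:01"]

    def test_some_allele_always_survives(self, cfg):
        # both exclusion rules require the partner's read set to be strictly
        # larger, so the maximal-cardinality allele of a gene can never be
        # excluded: kept lists are non-empty on arbitrary tables
        rng = np.random.default_rng(99)
        alleles = [f"A*{i+1:02d}:01" for i in range(4)]
        for _ in range(20):
            mapping = {}
            for i in range(rng.integers(1, 40)):
                k = rng.integers(1, len(alleles) + 1)
                mapping[f"r{i}"] = frozenset(
                    rng.choice(alleles, size=k, replace=False)
                )
            t = table(mapping, {"A": alleles})
            assert exclude_false_alleles(t, cfg)["A"]


class TestScoring:
    def het_table(self, n_specific=10):
        return table(
            reads_for({"a1": ({"A*01:01"}, n_specific),
                       "a2": ({"A*02:01"}, n_specific),
                       "both": ({"A*01:01", "A*02:01"}, 20)}),
            {"A": ["A*01:01", "A*02:01"]},
        )

    def test_true_heterozygous_pair_scores_two_per_pair(self, cfg):
        t = self.het_table()
        scores = score_pairs("A", t.candidates_by_gene["A"], set(), t, cfg)
        by_pair = {s.pair: s.score for s in scores}
        assert len(scores) == 3  # a1a1, a1a2, a2a2
        assert by_pair[("A*01:01", "A*02:01")] == 6
        assert by_pair[("A*01:01", "A*01:01")] == 5  # misses instance a2
        value, passed = quality_check(scores, cfg)
        assert value == 2.0 and passed

    @pytest.mark.parametrize("n_asr,expect_point", [(8, True), (9, False)])
    def test_unexplainable_asr_boundary(self, cfg, n_asr, expect_point):
        t = self.het_table(n_specific=n_asr)
        scores = score_pairs("A", t.candidates_by_gene["A"], set(), t, cfg)
        by_pair = {s.pair: s.score for s in scores}
        # the homozygous a1 pair leaves a2's ASRs unexplained: with 8 they
        # are tolerated (full score), with 9 the instance point is lost
        assert (by_pair[("A*01:01", "A*01:01")] == 6) is expect_point

    def test_identical_alleles_vacuous_tie(self, cfg):
        t = table(reads_for({"x": ({"A*01:01", "A*02:01"}, 15)}),
                  {"A": ["A*01:01", "A*02:01"]})
        scores = score_pairs("A", t.candidates_by_gene["A"], set(), t, cfg)
        assert len({s.score for s in scores}) == 1
        assert len(top_pairs(scores)) == 3

    def test_single_candidate_self_pair_passes(self, cfg):
        t = table(reads_for({"a": ({"A*01:01"}, 12)}), {"A": ["A*01:01"]})
        scores = score_pairs("A", ["A*01:01"], set(), t, cfg)
        assert [(s.pair, s.score) for s in scores] == [(("A*01:01", "A*01:01"), 2)]
        assert quality_check(scores, cfg) == (2.0, True)

    def test_pool_explains_cross_gene_reads(self, cfg):
        t = table(
            reads_for({"a1": ({"A*01:01"}, 10),
                       "cross": ({"A*02:01", "B*01:01"}, 10)}),
            {"A": ["A*01:01", "A*02:01"], "B": ["B*01:01"]},
        )
        no_pool = {s.pair: s.score
                   for s in score_pairs("A", t.candidates_by_gene["A"],
                                        set(), t, cfg)}
        with_pool = {s.pair: s.score
                     for s in score_pairs("A", t.candidates_by_gene["A"],
                                          {"B*01:01"}, t, cfg)}
        pair = ("A*01:01", "A*01:01")
        assert no_pool[pair] == 5 and with_pool[pair] == 6
        # own-gene alleles in the pool are not part of the explaining set
        own = {s.pair: s.score
               for s in score_pairs("A", t.candidates_by_gene["A"],
                                    {"A*02:01"}, t, cfg)}
        assert own[pair] == no_pool[pair]

    def test_score_monotone_in_pool(self, cfg):
        rng = np.random.default_rng(77)
        alleles = ["A*01:01", "A*02:01", "A*03:01"]
        others = ["B*01:01", "B*02:01"]
        mapping = {}
        universe = alleles + others
        for i in range(60):
            k = rng.integers(1, 4)
            mapping[f"r{i}"] = frozenset(rng.choice(universe, size=k,
                                                    replace=False))
        t = table(mapping, {"A": alleles, "B": others})
        small = {s.pair: s.score for s in score_pairs("A", alleles, set(), t, cfg)}
        big = {s.pair: s.score
               for s in score_pairs("A", alleles, set(others), t, cfg)}
        assert all(big[p] >= small[p] for p in small)

    def test_matches_bruteforce_oracle(self, cfg, std_db, std_run):
        """Scoring of the shared standard run, recomputed exhaustively from
        the raw read->allele map sets, matches the implementation."""
        sim, rs, report, diag = std_run
        t = build_asr_table(std_db, set(diag["stage2_survivors"]), rs, cfg)
        t = t.restrict(diag["post_exclusion"])
        pool = set(diag["seed_pool"])
        for gene in ("A", "B", "C"):
            cands = t.candidates_by_gene[gene]
            got = {s.pair: s.score
                   for s in score_pairs(gene, cands, pool, t, cfg)}
            want = oracles.score_pairs_bruteforce(
                gene, cands, pool, t.read_to_alleles, t.reads_of_allele,
                t.gene_of, cfg.max_unexplained_asr,
            )
            assert got == want


class TestIteratePool:
    def test_single_gene_fixed_point(self, cfg):
        t = table(
            reads_for({"a1": ({"A*01:01"}, 10), "a2": ({"A*02:01"}, 10)}),
            {"A": ["A*01:01", "A*02:01"]},
        )
        scores, tops, converged = iterate_pool(t, set(), cfg)
        assert converged
        assert tops["A"] == [("A*01:01", "A*02:01")]

    def test_cross_gene_pool_growth_promotes_truth(self, cfg):
        # gene-B truth is below the unique-read pool threshold, so only the
        # pool iteration can make B*01:01 available to explain the reads
        # cross-mapping to the false A candidate
        t = table(
            reads_for({"a1": ({"A*01:01"}, 10),
                       "cross": ({"A*02:01", "B*01:01"}, 10),
                       "b": ({"B*01:01"}, 5)}),
            {"A": ["A*01:01", "A*02:01"], "B": ["B*01:01"]},
        )
        pool0 = seed_real_pool(t, cfg)
        assert "B*01:01" not in pool0
        scores, tops, converged = iterate_pool(t, pool0, cfg)
        assert converged
        assert ("A*01:01", "A*01:01") in tops["A"]
        # final scores agree with the brute-force oracle at the final pool
        final_pool = pool0 | {a for prs in tops.values() for p in prs for a in p}
        want = oracles.score_pairs_bruteforce(
            "A", t.candidates_by_gene["A"], final_pool, t.read_to_alleles,
            t.reads_of_allele, t.gene_of, cfg.max_unexplained_asr,
        )
        assert {s.pair: s.score for s in scores["A"]} == want


class TestParalogCorrection:
    def call(self):
        return GeneCall(gene="A", alleles=("A*01:01", "A*02:01"),
                        ambiguity=[("A*01:01", "A*02:01")],
                        quality_value=2.0, quality="PASS",
                        top_score=6, n_pairs=3)

    def test_member_fully_explained_by_companion_removed(self, cfg):
        t = table(
            reads_for({"m1": ({"A*01:01"}, 5),
                       "m2h": ({"A*02:01", "H*01:01"}, 5)}),
            {"A": ["A*01:01", "A*02:01"], "H": ["H*01:01"]},
        )
        fixed = paralog_correction(self.call(), t, cfg)
        assert fixed.alleles == ("A*01:01",)

    def test_both_members_explained_no_removal(self, cfg):
        t = table(
            reads_for({"m1": ({"A*01:01", "H*01:01"}, 5),
                       "m2": ({"A*02:01", "H*01:01"}, 5)}),
            {"A": ["A*01:01", "A*02:01"], "H": ["H*01:01"]},
        )
        fixed = paralog_correction(self.call(), t, cfg)
        assert fixed.alleles == ("A*01:01", "A*02:01")

    def test_no_companion_gene_is_identity(self, cfg):
        t = table(
            reads_for({"m1": ({"A*01:01"}, 5), "m2": ({"A*02:01"}, 5)}),
            {"A": ["A*01:01", "A*02:01"]},
        )
        fixed = paralog_correction(self.call(), t, cfg)
        assert fixed.alleles == ("A*01:01", "A*02:01")


class TestQuality:
    def mk(self, scores):
        return [GenePairScore("A", (f"A*{i+1:02d}:01", f"A*{i+1:02d}:01"), s)
                for i, s in enumerate(scores)]

    def test_value_two_passes(self, cfg):
        value, passed = quality_check(self.mk([12, 7, 4, 3, 2, 1]), cfg)
        assert value == 2.0 and passed

    def test_value_below_two_fails(self, cfg):
        value, passed = quality_check(self.mk([9, 7, 4, 3, 2, 1]), cfg)
        assert value == 1.5 and not passed

    def test_zero_pairs_not_pass(self, cfg):
        assert quality_check([], cfg) == (0.0, False)
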