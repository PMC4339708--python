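"""Homeolog grouping, RBH orthologs, and expression categories."""

import numpy as np
import pytest

from bhlhkit.dupexpr import (
    ExpressionCategory,
    ExpressionProfile,
    HomeologEvidence,
    InputError,
    ParseError,
    SimilarityHit,
    TISSUES,
    VocabularyError,
    classify_expression,
    copy_number_histogram,
    expression_census,
    group_homeologs,
    read_blast_tab,
    reciprocal_best_hits,
)


def ev(a, b, ident, block="blk1"):
    return HomeologEvidence(a, b, ident, block)


class TestGroupHomeologs:
    GENES = ["g1", "g2", "g3", "g4", "g5"]

    def test_no_qualifying_evidence_gives_singletons(self):
        groups = group_homeologs(self.GENES, [ev("g1", "g2", 50.0)])
        assert all(g.copy_number == 1 for g in groups)
        assert len(groups) == 5

    def test_transitive_closure(self):
        groups = group_homeologs(self.GENES, [ev("g1", "g2", 95), ev("g2", "g3", 95)])
        sizes = sorted(g.copy_number for g in groups)
        assert sizes == [1, 1, 3]
        big = next(g for g in groups if g.copy_number == 3)
        assert big.members == ("g1", "g2", "g3")

    def test_identity_threshold_is_inclusive_boundary(self):
        below = group_homeologs(self.GENES, [ev("g1", "g2", 89.9)], min_identity=90)
        at = group_homeologs(self.GENES, [ev("g1", "g2", 90.0)], min_identity=90)
        assert max(g.copy_number for g in below) == 1
        assert max(g.copy_number for g in at) == 2

    def test_block_requirement(self):
        no_block = [HomeologEvidence("g1", "g2", 99.0, None)]
        assert max(g.copy_number for g in
                   group_homeologs(self.GENES, no_block, require_block=True)) == 1
        assert max(g.copy_number for g in
                   group_homeologs(self.GENES, no_block, require_block=False)) == 2

    def test_unknown_genes_reported(self):
        with pytest.raises(InputError, match="gX"):
            group_homeologs(self.GENES, [ev("g1", "gX", 95)])

    def test_partition_invariant_under_evidence_order(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        pairs = [ev(genes[int(rng.integers(20))], genes[int(rng.integers(20))], 95)
                 for _ in range(15)]
        pairs = [p for p in pairs if p.gene_a != p.gene_b]
        base = {g.members for g in group_homeologs(genes, pairs)}
        for _ in range(5):
            rng.shuffle(pairs)
            assert {g.members for g in group_homeologs(genes, pairs)} == base


class TestCopyNumberHistogram:
    def test_simple_spectrum(self):
        groups = group_homeologs(["a", "b", "c", "d", "e"], [ev("d", "e", 99)])
        hist = copy_number_histogram(groups)
        assert hist["histogram"] == {1: {"groups": 3, "genes": 3},
                                     2: {"groups": 1, "genes": 2}}
        assert hist["multi_copy_genes"] == 2

    def test_gene_count_conserved_on_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            pairs = [ev(genes[int(rng.integers(n))], genes[int(rng.integers(n))], 95)
                     for _ in range(n // 2)]
            pairs = [p for p in pairs if p.gene_a != p.gene_b]
            groups = group_homeologs(genes, pairs)
            hist = copy_number_histogram(groups)
            assert hist["total_genes"] == n
            # brute-force recount
            assert hist["multi_copy_genes"] == sum(
                g.copy_number for g in groups if g.copy_number > 1)


def hit(q, s, bits, e=1e-50, ident=80.0):
    return SimilarityHit(qseqid=q, sseqid=s, pident=ident, length=100,
                         evalue=e, bitscore=bits)


class TestReciprocalBestHits:
    def test_single_mutual_pair(self):
        assert reciprocal_best_hits([hit("x", "y", 200)], [hit("y", "x", 200)]) == [("x", "y")]

    def test_non_mutual_pair_suppressed(self):
        ab = [hit("x", "y", 200)]
        ba = [hit("y", "z", 300), hit("y", "x", 200)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_evalue_filter_is_strict(self):
        ab = [hit("x", "y", 200, e=1e-24)]
        ba = [hit("y", "x", 200, e=1e-24)]
        assert reciprocal_best_hits(ab, ba, max_evalue=1e-25) == []
        assert reciprocal_best_hits(ab, ba, max_evalue=1e-23) == [("x", "y")]

    def test_identity_filter(self):
        ab = [hit("x", "y", 200, ident=50.0)]
        ba = [hit("y", "x", 200, ident=50.0)]
        assert reciprocal_best_hits(ab, ba, min_identity=50.0) == []

    def test_tie_breaks_by_bits_then_evalue_then_subject(self):
        ab = [hit("x", "b", 200, e=1e-40), hit("x", "a", 200, e=1e-40)]
        ba = [hit("a", "x", 200), hit("b", "x", 200)]
        assert reciprocal_best_hits(ab, ba) == [("x", "a")]

    def test_symmetry_under_table_swap(self):
        rng = np.random.default_rng(7)
        ab, ba = [], []
        for i in range(20):
            q, s = f"q{int(rng.integers(5))}", f"s{int(rng.integers(5))}"
            ab.append(hit(q, s, float(rng.integers(50, 300))))
            ba.append(hit(s, q, float(rng.integers(50, 300))))
        fwd = set(reciprocal_best_hits(ab, ba))
        rev = {(x, y) for y, x in reciprocal_best_hits(ba, ab)}
        assert fwd == rev

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q\ts\t80\t100\t0\t0\t1\t100\t1\t100\t1e-50\t200\nshort\trow\n")
        with pytest.raises(ParseError, match="bad.tsv:2"):
            read_blast_tab(p)

    def test_blast_tab_round_trip(self, tmp_path):
        p = tmp_path / "ok.tsv"
        p.write_text("q\ts\t80.5\t100\t5\t1\t1\t100\t1\t100\t1e-50\t200.1\n")
        hits = read_blast_tab(p)
        assert hits[0].pident == 80.5 and hits[0].bitscore == 200.1


def profile(**levels):
    ab = {t: 0.0 for t in TISSUES}
    ab.update(levels)
    return ExpressionProfile("g", ab)


class TestClassifyExpression:
    @pytest.mark.parametrize("levels,expected", [
        ({}, ExpressionCategory.NOT_EXPRESSED),
        ({"nodule": 50, "root": 10}, ExpressionCategory.NODULE_PREFERENTIAL),
        ({"seed_mid": 60, "leaf": 10, "root": 10}, ExpressionCategory.SEED_ENRICHED),
        ({"root": 20, "leaf": 20, "seed_early": 20, "nodule": 20},
         ExpressionCategory.UBIQUITOUS),
        ({"pod_wall": 30}, ExpressionCategory.POD_WALL_ONLY),
        ({"root": 30, "leaf": 30}, ExpressionCategory.TISSUE_RESTRICTED),
    ])
    def test_category_rules(self, levels, expected):
        assert classify_expression(profile(**levels)).category == expected

    def test_seed_enrichment_boundary_is_inclusive(self):
        # 50 = 5 x 10 exactly -> enriched
        call = classify_expression(profile(seed_late=50, root=10, leaf=10))
        assert call.category == ExpressionCategory.SEED_ENRICHED
        call2 = classify_expression(profile(seed_late=49.9, root=10, leaf=10))
        assert call2.category != ExpressionCategory.SEED_ENRICHED

    def test_nodule_rule_ignores_root(self):
        call = classify_expression(profile(nodule=50, root=40))
        assert call.category == ExpressionCategory.NODULE_PREFERENTIAL
        leafy = classify_expression(profile(nodule=50, root=40, leaf=5))
        assert leafy.category != ExpressionCategory.NODULE_PREFERENTIAL

    def test_unknown_tissue_rejected(self):
        with pytest.raises(VocabularyError):
            ExpressionProfile("g", {"stem": 1.0})

    def test_every_profile_gets_one_category(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            ab = {t: float(rng.uniform(0, 20)) for t in TISSUES}
            call = classify_expression(ExpressionProfile("g", ab))
            assert isinstance(call.category, ExpressionCategory)
            assert call.expressed == bool(call.tissues_detected)

    def test_raising_threshold_never_creates_expression(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            ab = {t: float(rng.uniform(0, 3)) for t in TISSUES}
            p = ExpressionProfile("g", ab)
            low = classify_expression(p, detect_threshold=1.0)
            high = classify_expression(p, detect_threshold=2.5)
            if not low.expressed:
                assert not high.expressed
            assert high.tissues_detected <= low.tissues_detected


class TestExpressionCensus:
    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(11)
        calls = [classify_expression(ExpressionProfile(
            f"g{i}", {t: float(rng.uniform(0, 30)) for t in TISSUES}))
            for i in range(50)]
        census = expression_census(calls)
        assert sum(census["counts"].values()) == 50
        assert census["expressed_total"] == sum(c.expressed for c in calls)

    def test_planted_281_of_319(self):
        calls = ([classify_expression(profile(root=30, leaf=30, seed_mid=30))
                  for _ in range(281)]
                 + [classify_expression(profile()) for _ in range(38)])
        census = expression_census(calls)
        assert census["expressed_total"] == 281
        assert census["expressed_pct"] == 88.1
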