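"""Binding rules, censuses, distances, NJ trees, and family assignment."""

import io

import numpy as np
import pytest
import skbio

from bhlhkit.anatomy import DEFAULT_SCHEME, CanonicalDomain
from bhlhkit.binding import (
    BindingCategory,
    DistanceMatrix,
    UndefinedDistanceError,
    assign_family,
    binding_census,
    classify_binding,
    nj_tree,
    p_distance,
    pairwise_distances,
)
from bhlhkit.hmm import AMINO_ACIDS, MotifHit

N = DEFAULT_SCHEME.n_positions


def domain_from_basic(basic, fill="L", target="d"):
    aligned = basic + fill * (N - 13)
    return CanonicalDomain.from_aligned(target, aligned)


class TestClassifyBinding:
    @pytest.mark.parametrize("basic,category,raw", [
        # H5, E9, R12, R13, five basic residues -> G-box candidate
        ("ARARHAAAEAARR", BindingCategory.G_BOX_BINDER, True),
        # E9 + R12 but no H/K at 5 -> plain E-box binder
        ("RKARAAAAEAARA", BindingCategory.E_BOX_BINDER, False),
        ("AAAAAAAAAAAAA", BindingCategory.NON_BINDING_HLH, False),
        # no E9 but 5 basic residues -> candidate non-E-box binder
        ("RKRKRAAAAAAAA", BindingCategory.NON_EBOX_BINDER, False),
        # no E9, 4 or fewer basic residues -> atypical HLH
        ("RKRKAAAAAAAAA", BindingCategory.NON_BINDING_HLH, False),
    ])
    def test_rule_examples(self, basic, category, raw):
        call = classify_binding(domain_from_basic(basic))
        assert call.category == category
        assert call.gbox_rule_raw == raw

    def test_e9_without_r12_keeps_distinct_flags(self):
        # rare configuration: E9 present, R12 absent; it cannot be called
        # an E-box binder, but the flags stay readable in the record
        call = classify_binding(domain_from_basic("RKRKRAAAEAAAA"))
        assert call.e9 is True and call.r12 is False
        assert call.category == BindingCategory.NON_EBOX_BINDER

    def test_gap_at_rule_position_never_satisfies(self):
        call = classify_binding(domain_from_basic("ARARHAAA-AARR"))
        assert call.e9 is None
        assert call.category != BindingCategory.G_BOX_BINDER
        assert not call.gbox_rule_raw

    def test_every_domain_gets_exactly_one_category(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            basic = "".join(rng.choice(list(AMINO_ACIDS + "-"), size=13))
            call = classify_binding(domain_from_basic(basic))
            assert isinstance(call.category, BindingCategory)


class TestBindingCensus:
    def test_counts_and_percentages(self):
        calls = [classify_binding(domain_from_basic(b)) for b in
                 ("ARARHAAAEAARR", "ARARHAAAEAARR", "AAAAAAAAAAAAA")]
        c = binding_census(calls)
        assert c["counts"]["e9"] == 2
        assert c["counts"]["gbox_raw"] == 2
        assert c["categories"]["NON_BINDING_HLH"] == 1
        assert c["percentages"]["e9"] == 66.7

    def test_nesting_invariant_under_fuzzing(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            calls = [classify_binding(domain_from_basic(
                "".join(rng.choice(list(AMINO_ACIDS), size=13))))
                for _ in range(40)]
            c = binding_census(calls)["counts"]
            gbox_and_r12 = sum(x.gbox_rule_raw and bool(x.r12) for x in calls)
            assert gbox_and_r12 <= c["e9_and_r12"] <= c["e9"]
            assert sum(binding_census(calls)["categories"].values()) == len(calls)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        calls = [classify_binding(domain_from_basic(
            "".join(rng.choice(list(AMINO_ACIDS), size=13)))) for _ in range(25)]
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert binding_census(calls) == binding_census(shuffled)


class TestDistances:
    def test_identical_sequences_zero(self):
        assert p_distance("ACDE", "ACDE") == (0.0, 4)

    def test_quarter_mismatch(self):
        p, n = p_distance("AAAA", "AAAV")
        assert p == 0.25 and n == 4

    def test_gaps_excluded_from_shared_columns(self):
        p, n = p_distance("AC-E", "ACD-")
        assert n == 2 and p == 0.0

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("A-", "-A")

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = "".join(rng.choice(list(AMINO_ACIDS + "-"), size=40))
            b = "".join(rng.choice(list(AMINO_ACIDS + "-"), size=40))
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                continue
            expect = sum(x != y for x, y in shared) / len(shared)
            assert p_distance(a, b)[0] == pytest.approx(expect)

    def test_poisson_correction_exceeds_p(self):
        rows = [("a", "AAAAAAAAAAAAAAAAAAAAAA"), ("b", "AAAAAAAAAAAAAAAAVVVVVV")]
        dp = pairwise_distances(rows, model="p")
        dpois = pairwise_distances(rows, model="poisson")
        assert dpois.matrix[0, 1] > dp.matrix[0, 1] > 0

    def test_low_overlap_flagged(self):
        rows = [("a", "ACDE" + "-" * 30), ("b", "ACDE" + "-" * 30)]
        dm = pairwise_distances(rows)
        assert ("a", "b") in dm.low_overlap_pairs


def _tree(newick):
    return skbio.TreeNode.read(io.StringIO(newick))


def random_additive_matrix(rng, n_taxa):
    """Distances induced by a random binary tree with positive branch lengths."""
    ids = [f"t{i}" for i in range(n_taxa)]
    nodes = [skbio.TreeNode(name=i) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = skbio.TreeNode(children=[a, b])
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = nodes[0]
    dm = tree.tip_tip_distances()
    order = [dm.ids.index(i) for i in ids]
    return tree, DistanceMatrix(ids, dm.data[np.ix_(order, order)], "p")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = _tree(nj_tree(DistanceMatrix(list("ABC"), m, "p")))
        lengths = {t.name: t.length for t in tree.tips()}
        # v_A = (d_AB + d_AC - d_BC) / 2, etc.
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                           "C": pytest.approx(3.0)}

    def test_four_taxon_additive_worked_example(self):
        ids = list("ABCD")
        d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        m = np.zeros((4, 4))
        for (a, b), v in d.items():
            i, j = ids.index(a), ids.index(b)
            m[i, j] = m[j, i] = v
        tree = _tree(nj_tree(DistanceMatrix(ids, m, "p")))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0), "D": pytest.approx(4.0)}
        # AB|CD split with internal branch 1
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} in ({"A", "B"}, {"C", "D"})
        internal = [n.length for n in tree.non_tips() if n.length]
        assert any(l == pytest.approx(1.0) for l in internal)

    def test_recovers_topology_of_additive_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            true_tree, dm = random_additive_matrix(rng, int(rng.integers(5, 9)))
            inferred = _tree(nj_tree(dm))
            true_tree.unroot()
            assert true_tree.compare_rfd(inferred) == 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))


class TestAssignFamily:
    @pytest.fixture()
    def refs(self):
        rng = np.random.default_rng(21)
        out = []
        for fam in ("VIIa/b", "X", "XV"):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=N))
            out.append((fam, f"ref_{fam}", seq))
        return out

    def test_exact_reference_match(self, refs):
        fam, rid, seq = refs[0]
        dom = CanonicalDomain.from_aligned("q", seq)
        fa = assign_family(dom, refs)
        assert fa.family == fam and fa.distance == 0.0 and not fa.ambiguous

    def test_equidistant_tie_breaks_lexicographically_and_flags_ambiguity(self):
        dom = CanonicalDomain.from_aligned("q", "A" * N)
        refs = [("Zeta", "rZ", "V" * 10 + "A" * (N - 10)),
                ("Alpha", "rA", "A" * (N - 10) + "V" * 10)]
        assert (p_distance(dom.aligned_string(), refs[0][2])[0]
                == p_distance(dom.aligned_string(), refs[1][2])[0])
        fa = assign_family(dom, refs)
        assert fa.family == "Alpha"  # lexicographically smaller label wins the tie
        assert fa.margin == 0.0
        assert fa.ambiguous

    def test_motif_corroboration_resolves_narrow_margin(self, refs):
        fam_x = next(r for r in refs if r[0] == "X")
        dom = CanonicalDomain.from_aligned("q", fam_x[2])
        hit = MotifHit(motif="Motif40", target_id="q", bit_score=80.0,
                       evalue=1e-9, env_start=0, env_end=29)
        fa = assign_family(dom, refs, motif_hits=[hit], margin_threshold=10.0)
        assert fa.family == "X"
        assert fa.motif_support == ["Motif40"]
        assert not fa.ambiguous  # motif support overrides the narrow margin

    def test_invariant_to_reference_order(self, refs):
        rng = np.random.default_rng(33)
        dom = CanonicalDomain.from_aligned(
            "q", "".join(rng.choice(list(AMINO_ACIDS), size=N)))
        base = assign_family(dom, refs)
        shuffled = list(refs)[::-1]
        assert assign_family(dom, shuffled) == base

    def test_no_references_rejected(self):
        dom = CanonicalDomain.from_aligned("q", "A" * N)
        with pytest.raises(ValueError):
            assign_family(dom, [])
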