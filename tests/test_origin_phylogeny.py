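"""Distances, neighbor joining, sister-clade classification, census algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from egtcensus import origin_phylogeny as op
from egtcensus import synthetic_data as sd
from egtcensus.formats_io import SequenceRecord, read_newick, write_newick

GROUPS = {
    "C1": "cyanobacteria", "C2": "cyanobacteria", "C3": "cyanobacteria",
    "E1": "reference_eukaryote", "E2": "reference_eukaryote",
    "B1": "other_bacteria", "B2": "other_bacteria",
    "Q2": "query",
}


def unrooted_bipartitions(tree):
    """Non-trivial splits as frozensets of the smaller side (canonical)."""
    leaves = frozenset(tree.leaf_labels())
    out = set()

    def walk(node):
        s = frozenset(node.leaf_labels())
        if 1 < len(s) < len(leaves) - 1:
            out.add(min(s, leaves - s, key=lambda x: tuple(sorted(x))))
        for c in node.children:
            walk(c)

    walk(tree)
    return out


class TestKimuraDistance:
    def test_zero(self):
        assert op.kimura_distance(0.0) == 0.0

    def test_closed_form(self):
        assert op.kimura_distance(0.5) == pytest.approx(-math.log(0.45))
        assert op.kimura_distance(0.5) == pytest.approx(0.7985, abs=1e-4)

    def test_cap(self):
        assert op.kimura_distance(0.9) == 5.0
        assert op.kimura_distance(0.85) == 5.0


class TestProteinDistanceMatrix:
    def test_identical_family_is_zero(self):
        recs = [SequenceRecord(id=f"p{i}", seq="MKVLAAGHRT" * 5, kind="protein")
                for i in range(3)]
        dist, ids = op.protein_distance_matrix(recs)
        assert ids == ["p0", "p1", "p2"]
        assert np.allclose(dist, 0.0)

    def test_too_small_family(self):
        recs = [SequenceRecord(id=f"p{i}", seq="MKVL", kind="protein") for i in range(2)]
        with pytest.raises(ValueError, match="≥ 3"):
            op.protein_distance_matrix(recs)

    def test_alignment_less_pair_named(self):
        recs = [
            SequenceRecord(id="a", seq="AAAA", kind="protein"),
            SequenceRecord(id="b", seq="AAAA", kind="protein"),
            SequenceRecord(id="c", seq="PPPP", kind="protein"),
        ]
        with pytest.raises(ValueError, match=r"pair \(a, c\)"):
            op.protein_distance_matrix(recs)


class TestNjTree:
    def test_four_taxon_additive_split(self):
        # d(A,B)=2, d(C,D)=2, cross distances 4 → split AB|CD
        dist = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                        dtype=float)
        tree = op.nj_tree(dist, ["A", "B", "C", "D"])
        assert unrooted_bipartitions(tree) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        dist = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = op.nj_tree(dist, ["A", "B", "C"])
        assert sorted(tree.leaf_labels()) == ["A", "B", "C"]

    def test_non_symmetric_rejected(self):
        dist = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            op.nj_tree(dist, ["A", "B", "C"])

    def test_additive_matrices_recover_topology(self, rng):
        for _ in range(25):
            dist, ids, truth = sd.random_additive_matrix(6, rng)
            recovered = op.nj_tree(dist, ids)
            assert unrooted_bipartitions(recovered) == unrooted_bipartitions(truth)


class TestClassifyOrigin:
    @pytest.mark.parametrize("nwk,call,fraction", [
        ("((Q,(C1,C2)),(E1,B1));", "cyanobacterial", 1.0),
        ("((Q,(E1,E2)),(C1,B1));", "non_cyanobacterial", 0.0),
        ("((Q,(C1,E1)),(B1,B2));", "ambiguous", 0.5),
    ])
    def test_worked_examples(self, nwk, call, fraction):
        res = op.classify_origin(read_newick(nwk), "Q", GROUPS)
        assert res.call == call
        assert res.sister_cyano_fraction == fraction

    def test_rerooting_invariance(self):
        rooted_variants = [
            "((Q,(C1,C2,C3)),((E1,E2),(B1,B2)));",
            "((E1,E2),((B1,B2),((C1,C2,C3),Q)));",
            "((B1,B2),((Q,(C1,C2,C3)),(E1,E2)));",
        ]
        calls = [op.classify_origin(read_newick(v), "Q", GROUPS) for v in rooted_variants]
        assert len({(c.call, c.sister_cyano_fraction) for c in calls}) == 1
        assert calls[0].call == "cyanobacterial"

    def test_same_species_paralogs_excluded(self):
        res = op.classify_origin(read_newick("((Q,(Q2,C1)),((E1,E2),(B1,B2)));"),
                                 "Q", GROUPS)
        assert res.call == "cyanobacterial"
        assert res.sister_cyano_fraction == 1.0
        assert res.n_sister_leaves == 1  # Q2 not counted

    def test_all_paralog_sister_is_ambiguous(self):
        groups = dict(GROUPS)
        res = op.classify_origin(read_newick("((Q,Q2),((E1,E2),(B1,B2)));"), "Q", groups)
        assert res.call == "ambiguous"

    def test_missing_query_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            op.classify_origin(read_newick("((C1,C2),(E1,B1));"), "Q", GROUPS)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="without taxon group"):
            op.classify_origin(read_newick("((Q,ZZ),(E1,B1));"), "Q", GROUPS)


class TestEndToEndFamilies:
    def test_planted_donor_recovered(self):
        families, groups, truths = sd.gen_families(n_families=6, seed=17, protein_len=300, tree_depth=0.2)
        for truth in truths:
            call = op.classify_family(families[truth.family_id], truth.query_gene_id,
                                      groups)
            expected = ("cyanobacterial" if truth.donor == "cyanobacterial"
                        else "non_cyanobacterial")
            assert call.call == expected, truth.family_id

    def test_mixed_sister_always_ambiguous(self):
        families, groups, truths = sd.gen_families(n_families=3, seed=23, mixed_sister=True, protein_len=300, tree_depth=0.2)
        for truth in truths:
            call = op.classify_family(families[truth.family_id], truth.query_gene_id,
                                      groups)
            assert call.call == "ambiguous", truth.family_id

    def test_true_tree_classification_matches_nj_classification(self):
        families, groups, truths = sd.gen_families(n_families=4, seed=31, protein_len=300, tree_depth=0.2)
        for truth in truths:
            via_truth = op.classify_origin(truth.true_tree, truth.query_gene_id, groups)
            via_nj = op.classify_family(families[truth.family_id],
                                        truth.query_gene_id, groups)
            assert via_truth.call == via_nj.call


class TestBuildCensus:
    def call(self, gene, call="cyanobacterial"):
        return op.OriginCall(gene_id=gene, call=call, sister_cyano_fraction=1.0,
                             n_sister_leaves=2)

    def test_worked_example(self):
        summary = op.build_census(
            [self.call("n1"), self.call("n2")],
            {("n1", "p1"), ("n3", "p2")},
            ["p1", "p2", "p3"],
        )
        assert (summary.n_cyano_recruits, summary.n_nuclear_with_plastid_homolog,
                summary.n_both) == (2, 2, 1)
        assert (summary.n_plastid_proteins, summary.n_plastid_with_nuclear_homolog,
                summary.n_plastid_with_cyano_nuclear_homolog) == (3, 2, 1)

    def test_no_recruits(self):
        summary = op.build_census([], set(), ["p1"])
        assert summary.n_cyano_recruits == 0
        assert summary.n_both == 0

    def test_expression_percentage(self):
        summary = op.build_census([self.call("n1"), self.call("n2")], set(), [],
                                  expression={"n1": True, "n2": False})
        assert summary.pct_recruits_expressed == 50.0

    @given(st.data())
    def test_invariant_inequalities_on_random_relations(self, data):
        genes = [f"n{i}" for i in range(8)]
        plastid = [f"p{i}" for i in range(5)]
        recruits = data.draw(st.sets(st.sampled_from(genes)))
        pairs = data.draw(st.sets(st.tuples(st.sampled_from(genes),
                                            st.sampled_from(plastid))))
        calls = [self.call(g) for g in recruits]
        summary = op.build_census(calls, pairs, plastid)
        assert summary.n_both <= min(summary.n_cyano_recruits,
                                     summary.n_nuclear_with_plastid_homolog)
        assert (summary.n_plastid_with_cyano_nuclear_homolog
                <= summary.n_plastid_with_nuclear_homolog
                <= summary.n_plastid_proteins)
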