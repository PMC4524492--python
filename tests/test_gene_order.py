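"""Signed orders, sidedness, canonical pairs, shared-pair matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastarch import gene_order as go
from plastarch import simulate as sim
from plastarch.genome_io import GeneFeature, GenomeRecord

from oracles import sidedness_by_sign_changes


def _order(signs, taxon="t"):
    return go.SignedGeneOrder(taxon, [(f"g{i}", s) for i, s in enumerate(signs)])


class TestSidedness:
    def test_all_one_strand_gives_cs_one(self):
        r = go.sidedness_index(_order([1] * 10))
        assert r.n_sb == 1 and r.cs == 1.0

    def test_alternating_circular_gives_cs_zero(self):
        r = go.sidedness_index(_order([1, -1, 1, -1, 1, -1]))
        assert r.n_sb == 6 and r.cs == 0.0

    def test_wraparound_run_merges(self):
        # circular (+,+,-,-,+): first and last runs join -> 2 blocks
        r = go.sidedness_index(_order([1, 1, -1, -1, 1]))
        assert r.n_sb == 2 and r.cs == 0.75

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            go.sidedness_index(_order([1]))

    def test_matches_sign_change_oracle_on_random_orders(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 40))
            signs = list(rng.choice([1, -1], size=n))
            r = go.sidedness_index(_order(signs))
            assert r.n_sb == sidedness_by_sign_changes(signs)

    def test_flipping_inside_large_block_decreases_cs(self, rng):
        signs = [1] * 8 + [-1] * 4
        base = go.sidedness_index(_order(signs)).cs
        signs2 = list(signs)
        signs2[3] = -1  # interior of an 8-gene sided block
        assert go.sidedness_index(_order(signs2)).cs < base


class TestCanonicalPairs:
    def test_circular_three_gene_order(self):
        o = go.SignedGeneOrder("t", [("a", 1), ("b", 1), ("c", -1)])
        pairs = {str(p) for p in go.canonical_pairs(o)}
        want = {str(go.AdjacencyPair.canonical(x, y)) for x, y in
                [(("a", 1), ("b", 1)), (("b", 1), ("c", -1)), (("c", -1), ("a", 1))]}
        assert pairs == want and len(pairs) == 3

    def test_reflection_canonicalization(self):
        p1 = go.AdjacencyPair.canonical(("b", 1), ("a", -1))
        p2 = go.AdjacencyPair.canonical(("a", 1), ("b", -1))
        assert p1 == p2

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from([1, -1]), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_pair_set_invariant_under_reflection(self, signs, rnd):
        names = [f"g{i}" for i in range(len(signs))]
        rnd.shuffle(names)
        o = go.SignedGeneOrder("t", list(zip(names, signs)))
        assert go.canonical_pairs(o) == go.canonical_pairs(o.reflected())

    def test_count_equals_n_for_distinct_symbols(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            o = _order(list(rng.choice([1, -1], size=n)))
            assert len(go.canonical_pairs(o)) == n


class TestSharedPairMatrix:
    def test_identical_orders_all_present(self):
        o1 = _order([1, 1, -1, 1], "a")
        o2 = _order([1, 1, -1, 1], "b")
        m = go.shared_pair_matrix([o1, o2], min_share=2)
        assert (m.table == 1).all().all()
        assert len(m.pairs) == 4

    def test_disjoint_gene_sets_empty(self):
        o1 = go.SignedGeneOrder("a", [("x1", 1), ("x2", 1)])
        o2 = go.SignedGeneOrder("b", [("y1", 1), ("y2", 1)])
        m = go.shared_pair_matrix([o1, o2], min_share=2)
        assert m.table.empty

    def test_min_share_below_two_rejected(self):
        with pytest.raises(ValueError):
            go.shared_pair_matrix([_order([1, 1], "a"), _order([1, 1], "b")], min_share=1)

    def test_taxon_order_invariance(self):
        orders = [_order([1, -1, 1, 1], t) for t in "abc"]
        m1 = go.shared_pair_matrix(orders, min_share=2).table
        m2 = go.shared_pair_matrix(orders[::-1], min_share=2).table
        assert m1.equals(m2[m1.columns])

    def test_missing_gene_flagged_na(self):
        o1 = go.SignedGeneOrder("a", [("x", 1), ("y", 1), ("z", 1)])
        o2 = go.SignedGeneOrder("b", [("x", 1), ("y", 1), ("z", 1)])
        o3 = go.SignedGeneOrder("c", [("x", 1), ("y", 1)])  # z lost
        m = go.shared_pair_matrix([o1, o2, o3], min_share=2)
        col = m.table["c"]
        assert col.isna().any()

    def test_single_inversion_separates_exactly_breakpoint_pairs(self, rng):
        cfg = sim.SimConfig(seed=9, ir_gene_count=0, n_genes=20,
                            genome_length_target=35000)
        anc = sim.make_ancestor(cfg, np.random.default_rng(9))
        import copy
        child = copy.deepcopy(anc)
        ev = sim._sample_event(child, "inversion", cfg, np.random.default_rng(4))
        sim.apply_event(child, ev)
        p_parent = go.canonical_pairs(anc.gene_order("p"))
        p_child = go.canonical_pairs(child.gene_order("c"))
        diff = p_parent ^ p_child
        # one inversion breaks at most 2 adjacencies and forms at most 2 new
        assert 0 < len(diff) <= 4


class TestExtractionAndCore:
    def test_feature_order_and_polarity(self):
        feats = [GeneFeature("psbA", "psbA", "CDS", 1, [(10, 40)]),
                 GeneFeature("rbcL", "rbcL", "CDS", -1, [(50, 80)]),
                 GeneFeature("rrs", "rrs", "rRNA", 1, [(90, 120)])]
        g = GenomeRecord(taxon="t", sequence="A" * 200, features=feats)
        o = go.extract_signed_gene_order(g, gene_filter=None, collapse_ir=False)
        assert o.genes == [("psbA", 1), ("rbcL", -1), ("rrs", 1)]

    def test_duplicate_outside_ir_keeps_first(self):
        feats = [GeneFeature("a", "a", "CDS", 1, [(0, 10)]),
                 GeneFeature("rrs", "rrs", "rRNA", 1, [(20, 30)]),
                 GeneFeature("b", "b", "CDS", 1, [(40, 50)]),
                 GeneFeature("rrs", "rrs", "rRNA", -1, [(60, 70)])]
        g = GenomeRecord(taxon="t", sequence="A" * 100, features=feats)
        o = go.extract_signed_gene_order(g, gene_filter=None, collapse_ir=False)
        assert o.genes == [("a", 1), ("rrs", 1), ("b", 1)]

    def test_empty_filter_result_raises(self):
        g = GenomeRecord(taxon="t", sequence="A" * 100, features=[
            GeneFeature("a", "a", "CDS", 1, [(0, 10)])])
        with pytest.raises(ValueError):
            go.extract_signed_gene_order(g, gene_filter={"nonexistent"})

    def test_extraction_matches_simulator_truth(self, ancestor, ancestor_realized):
        rec, ann = ancestor_realized
        o = go.extract_signed_gene_order(rec, gene_filter=None, collapse_ir=True, ir=ann)
        assert o.genes == ancestor.gene_order().genes

    def test_core_gene_set_intersection(self):
        def mk(taxon, syms, complete=True):
            feats = [GeneFeature(s, s, "CDS", 1, [(i * 10, i * 10 + 5)])
                     for i, s in enumerate(syms)]
            return GenomeRecord(taxon=taxon, sequence="A" * 200, features=feats,
                                complete=complete)
        g1 = mk("a", ["x", "y", "z"])
        g2 = mk("b", ["x", "y"])
        g3 = mk("c", ["x"], complete=False)  # excluded
        assert go.core_gene_set([g1, g2, g3]) == {"x", "y"}
        assert go.core_gene_set([g1]) == {"x", "y", "z"}


def test_grimm_round_trip(tmp_path):
    orders = [go.SignedGeneOrder("tax1", [("psbA", 1), ("rbcL", -1), ("rrs", 1)]),
              go.SignedGeneOrder("tax2", [("rrs", -1), ("psbA", 1)])]
    p = tmp_path / "orders.grimm"
    go.write_grimm(orders, p)
    back = go.read_grimm(p)
    assert [(o.taxon, o.genes) for o in back] == [(o.taxon, o.genes) for o in orders]
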