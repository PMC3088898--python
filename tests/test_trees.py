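"""Tree structure, Newick round trips, bipartition algebra, NNI moves,
consensus and the bipartition-frequency convergence diagnostic."""

import itertools

import dendropy
import numpy as np
import pytest

from streptophylo import trees as T
from tests.conftest import random_trees


def brute_force_bipartitions(tree):
    """Oracle: delete each internal edge and collect the leaf components."""
    out = set()
    taxa = tree.taxa
    for child in tree.internal_edges():
        below = frozenset(l.name for l in _leaves(child))
        if 1 < len(below) < len(taxa) - 1:
            out.add(T.Bipartition.make(below, taxa))
    return out


def _leaves(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


class TestNewick:
    def test_four_leaf_parse(self):
        t = T.parse_newick("((A:1,B:1):1,(C:1,D:1));")
        assert t.n_leaves == 4
        assert len(t.internal_edges()) == 1
        assert t.is_binary()

    def test_round_trip_isomorphic(self):
        for tree in random_trees(7, 5, seed=3):
            again = T.parse_newick(T.write_newick(tree))
            assert T.rf_distance(tree, again) == 0
            orig = {n.name: n.length for n in tree.leaves()}
            back = {n.name: n.length for n in again.leaves()}
            assert back == pytest.approx(orig, rel=1e-5)

    def test_support_parsing_matches_dendropy(self):
        s = "((A,B)95,(C,D));"
        t = T.parse_newick(s)
        ours = [n.support for n in t.internal_edges()]
        dt = dendropy.Tree.get(data=s, schema="newick")
        theirs = [float(n.label) for n in dt.preorder_node_iter()
                  if n.label and not n.is_leaf()]
        assert ours == theirs == [95.0]

    def test_pp_scale(self):
        t = T.parse_newick("((A,B)0.97,(C,D));", support_scale="pp")
        assert t.internal_edges()[0].support == pytest.approx(97.0)
        assert t.support_kind == "pp"

    def test_malformed_reports_offset(self):
        with pytest.raises(T.NewickError) as err:
            T.parse_newick("((A,B),(C,D);")
        assert err.value.offset is not None

    def test_missing_semicolon(self):
        with pytest.raises(T.NewickError):
            T.parse_newick("((A,B),(C,D))")

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(T.TreeError, match="duplicate"):
            T.parse_newick("((A,A),(C,D));")

    def test_negative_length_rejected(self):
        with pytest.raises(T.TreeError, match="negative"):
            T.parse_newick("((A:-0.1,B:1):1,(C:1,D:1));")

    def test_absent_length_is_sentinel_not_zero(self):
        t = T.parse_newick("((A,B):1,(C,D):1);")
        assert all(n.length is None for n in t.leaves())

    def test_whitespace_names_escaped_on_output(self):
        t = T.parse_newick("((A,B):1,(C,D):1);")
        t.leaves()[0].name = "Chara vulgaris"
        assert "Chara_vulgaris" in T.write_newick(t)


class TestBipartitions:
    def test_quartet(self):
        t = T.parse_newick("((A,B),(C,D));")
        (b,) = T.bipartitions(t)
        assert set(map(frozenset, b.blocks)) == {frozenset("AB"), frozenset("CD")}

    def test_caterpillar_count(self):
        t = T.parse_newick("(A,(B,(C,(D,(E,F)))));")
        assert len(T.bipartitions(t.deroot())) == 3

    @pytest.mark.parametrize("n_leaves", [5, 6, 8, 9])
    def test_matches_edge_deletion_oracle(self, n_leaves):
        for tree in random_trees(n_leaves, 4, seed=n_leaves):
            assert T.bipartitions(tree) == brute_force_bipartitions(tree)
            assert len(T.bipartitions(tree)) == n_leaves - 3

    def test_small_trees_empty(self):
        assert T.bipartitions(T.parse_newick("(A,B,C);")) == set()


class TestCompatibility:
    def test_trivial_cases(self):
        t = T.parse_newick("((A,B),(C,D));")
        ab = T.Bipartition.make({"A", "B"}, t.taxa)
        ac = T.Bipartition.make({"A", "C"}, t.taxa)
        assert T.is_compatible(ab, t)
        assert not T.is_compatible(ac, t)

    def test_taxon_mismatch_instructs_restriction(self):
        t = T.parse_newick("((A,B),(C,D));")
        b = T.Bipartition.make({"A", "B"}, {"A", "B", "C", "E"})
        with pytest.raises(T.TreeError, match="restrict"):
            T.is_compatible(b, t)

    def test_random_splits_vs_four_intersection_oracle(self):
        tree = random_trees(7, 1, seed=77)[0]
        taxa = sorted(tree.taxa)
        rng = np.random.default_rng(5)
        tree_splits = T.bipartitions(tree)
        for _ in range(20):
            size = int(rng.integers(2, len(taxa) - 1))
            side = frozenset(rng.choice(taxa, size=size, replace=False))
            b = T.Bipartition.make(side, taxa)
            oracle = all(
                any(len(x & y) == 0
                    for x in b.blocks for y in s.blocks)
                for s in tree_splits)
            assert T.is_compatible(b, tree) == oracle


class TestRFDistance:
    def test_identity_and_quartet(self):
        t1 = T.parse_newick("((A,B),(C,D));")
        t2 = T.parse_newick("((A,C),(B,D));")
        assert T.rf_distance(t1, t1) == 0
        assert T.rf_distance(t1, t2) == 2

    def test_matches_dendropy(self):
        tns = dendropy.TaxonNamespace()
        for a, b in itertools.combinations(random_trees(8, 4, seed=9), 2):
            ours = T.rf_distance(a, b)
            da = dendropy.Tree.get(data=T.write_newick(a), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=T.write_newick(b), schema="newick",
                                   taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            assert ours == dendropy.calculate.treecompare.symmetric_difference(da, db)

    def test_leaf_set_mismatch(self):
        with pytest.raises(T.TreeError):
            T.rf_distance(T.parse_newick("((A,B),(C,D));"),
                          T.parse_newick("((A,B),(C,E));"))


class TestNNI:
    def test_quartet_has_two_neighbors(self):
        t = T.parse_newick("((A:1,B:2):3,(C:4,D:5));")
        nbrs = T.nni_neighbors(t)
        assert len(nbrs) == 2
        splits = {frozenset(map(frozenset, next(iter(T.bipartitions(n))).blocks))
                  for n in nbrs}
        assert splits == {frozenset({frozenset("AC"), frozenset("BD")}),
                          frozenset({frozenset("AD"), frozenset("BC")})}

    @pytest.mark.parametrize("n_leaves", [5, 6, 7])
    def test_count_distinct_and_rf2(self, n_leaves):
        tree = random_trees(n_leaves, 1, seed=n_leaves + 50)[0]
        nbrs = T.nni_neighbors(tree)
        assert len(nbrs) == 2 * (n_leaves - 3)
        keys = {frozenset(T.bipartitions(n)) for n in nbrs}
        assert len(keys) == len(nbrs)          # all distinct topologies
        for n in nbrs:
            assert T.rf_distance(tree, n) == 2

    def test_polytomy_rejected_then_resolvable(self):
        star = T.parse_newick("(A,B,C,D,E);")
        with pytest.raises(T.TreeError, match="binary"):
            T.nni_neighbors(star)
        resolved = T.resolve_polytomies(star, seed=1)
        assert resolved.is_binary()
        assert T.resolve_polytomies(star, seed=1).taxa == star.taxa
        same = T.resolve_polytomies(star, seed=1)
        assert T.rf_distance(resolved, same) == 0   # seed-deterministic


class TestConsensus:
    def test_identical_sample_is_identity(self):
        t = T.parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        cons = T.majority_consensus(T.TreeSample([t.copy() for _ in range(3)]))
        assert T.rf_distance(cons, t) == 0
        assert all(e.support == 100.0 for e in cons.internal_edges())

    def test_two_thirds_majority_hand_count(self):
        t1 = T.parse_newick("((A,B),(C,D),E);")
        t2 = T.parse_newick("((A,C),(B,D),E);")
        cons = T.majority_consensus(T.TreeSample([t1, t1.copy(), t2]))
        bips = {b: e for b in T.bipartitions(cons) for e in [None]}
        ab = T.Bipartition.make({"A", "B"}, t1.taxa)
        assert ab in bips
        # both AB|CDE and CD|ABE occur in 2 of 3 trees
        sup = [e.support for e in cons.internal_edges() if e.support]
        assert sup == pytest.approx([200 / 3, 200 / 3])

    def test_empty_sample_errors(self):
        with pytest.raises(T.TreeError):
            T.majority_consensus(T.TreeSample([]))

    def test_greedy_extension_adds_compatible_minority(self):
        t1 = T.parse_newick("((A,B),(C,D),E);")
        t2 = T.parse_newick("((A,B),(C,E),D);")
        sample = T.TreeSample([t1, t2])
        strict = T.majority_consensus(sample)
        greedy = T.majority_consensus(sample, greedy=True)
        assert len(T.bipartitions(greedy)) > len(T.bipartitions(strict))


class TestMaxdiff:
    def test_identical_and_disjoint(self):
        t1 = T.parse_newick("((A,B),(C,D),E);")
        t2 = T.parse_newick("((A,C),(B,D),E);")
        s1 = T.TreeSample([t1, t1.copy()])
        assert T.bipartition_maxdiff(s1, s1) == 0.0
        s2 = T.TreeSample([t2, t2.copy()])
        assert T.bipartition_maxdiff(s1, s2) == 1.0

    def test_hand_counted_frequencies(self):
        # AB|CDE: 0.8 vs 0.7 is impossible with tiny samples; use 4 vs 2 of 4
        t_ab = T.parse_newick("((A,B),(C,D),E);")     # AB|CDE and CD|ABE
        t_alt = T.parse_newick("((A,B),(C,E),D);")    # AB|CDE and CE|ABD
        s1 = T.TreeSample([t_ab, t_ab.copy(), t_ab.copy(), t_alt])
        s2 = T.TreeSample([t_ab, t_alt.copy(), t_alt.copy(), t_alt.copy()])
        # AB: 1.0 vs 1.0; CD: 0.75 vs 0.25; CE: 0.25 vs 0.75
        assert T.bipartition_maxdiff(s1, s2) == pytest.approx(0.5)

    def test_symmetry_and_triangle_bound(self):
        trees = random_trees(6, 9, seed=13)
        a = T.TreeSample(trees[:3])
        b = T.TreeSample(trees[3:6])
        c = T.TreeSample(trees[6:])
        ab = T.bipartition_maxdiff(a, b)
        assert ab == T.bipartition_maxdiff(b, a)
        assert T.bipartition_maxdiff(a, c) <= ab + T.bipartition_maxdiff(b, c) + 1e-12


class TestRestrict:
    def test_prune_sums_lengths(self):
        t = T.parse_newick("((A:1,B:2):3,(C:4,D:5):6,E:7);")
        r = T.restrict(t, {"A", "C", "D", "E"})
        assert r.taxa == frozenset("ACDE")
        lengths = {n.name: n.length for n in r.leaves()}
        assert lengths["A"] == pytest.approx(4.0)   # 1 + 3 after suppression

    def test_unknown_taxon(self):
        t = T.parse_newick("((A,B),(C,D));")
        with pytest.raises(T.TreeError):
            T.restrict(t, {"A", "Z"})
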