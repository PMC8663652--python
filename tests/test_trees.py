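import itertools

import pytest

from morphoclad import (
    Tree,
    count_unrooted_topologies,
    enumerate_unrooted_topologies,
    nni_neighbors,
    strict_consensus,
    tbr_neighbors,
    tree_from_bipartitions,
    tree_from_newick,
    tree_to_newick,
)
from morphoclad.simulate import simulate_yule_tree


def quartet(a, b, c, d):
    """The unrooted tree ((a,b),(c,d))."""
    return Tree.from_edges(
        [(0, 4), (1, 4), (4, 5), (2, 5), (3, 5)],
        {0: a, 1: b, 2: c, 3: d},
    )


class TestEnumeration:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_count_matches_double_factorial(self, n):
        taxa = [f"t{i}" for i in range(n)]
        trees = list(enumerate_unrooted_topologies(taxa))
        assert len(trees) == count_unrooted_topologies(n)

    def test_topologies_distinct_by_bipartition_sets(self):
        taxa = [f"t{i}" for i in range(6)]
        trees = list(enumerate_unrooted_topologies(taxa))
        assert len({t for t in trees}) == 105

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_unrooted_topologies(["a", "b"]))


class TestCanonicalIdentity:
    def test_child_order_is_irrelevant(self):
        t1 = quartet("a", "b", "c", "d")
        t2 = quartet("b", "a", "d", "c")
        t3 = quartet("c", "d", "a", "b")
        assert t1 == t2 == t3
        assert hash(t1) == hash(t3)
        assert t1 != quartet("a", "c", "b", "d")

    def test_degree_two_internal_node_rejected(self):
        with pytest.raises(ValueError, match="degree 2"):
            Tree.from_edges([(0, 2), (2, 3), (3, 1)], {0: "a", 1: "b"})


class TestRooting:
    def test_outgroup_rooting_creates_ingroup_clade(self, study_fit):
        for t in study_fit.mpts:
            rv = t.root_on_outgroup("Laophontodes_typicus")
            (top,) = rv.children[rv.root]
            assert rv.clade_leaves(top) == t.leaves - {"Laophontodes_typicus"}

    def test_rooting_view_preserves_bipartitions(self):
        for seed in range(5):
            t = simulate_yule_tree(7, seed=seed)
            for leaf in sorted(t.leaves):
                rv = t.rooted_at(leaf)
                # rebuild from the rooted view and compare canonically
                edges = [(v, rv.parent[v]) for v in rv.order[1:]]
                again = Tree.from_edges(edges, rv.label)
                assert again == t

    def test_unknown_outgroup_raises(self):
        with pytest.raises(KeyError):
            quartet("a", "b", "c", "d").rooted_at("zz")


class TestRearrangements:
    def test_quartet_has_two_tbr_neighbors(self):
        t = quartet("a", "b", "c", "d")
        nbs = set(tbr_neighbors(t))
        assert len(nbs) == 2
        assert t not in nbs

    @pytest.mark.parametrize("n,seed", [(6, 0), (7, 1), (8, 2)])
    def test_tbr_neighborhood_contains_nni(self, n, seed):
        t = simulate_yule_tree(n, seed=seed)
        assert set(nni_neighbors(t)) <= set(tbr_neighbors(t))

    def test_tbr_symmetry(self):
        t = simulate_yule_tree(6, seed=3)
        for nb in itertools.islice(tbr_neighbors(t), 10):
            assert t in set(tbr_neighbors(nb))


class TestConsensus:
    def test_identity_on_singleton(self):
        t = simulate_yule_tree(6, seed=4)
        assert strict_consensus([t]) == t

    def test_consensus_splits_are_shared_splits(self):
        trees = [simulate_yule_tree(7, seed=s) for s in range(4)]
        cons = strict_consensus(trees)
        expected = frozenset.intersection(*(t.bipartitions() for t in trees))
        assert cons.bipartitions() == expected
        for t in trees:
            assert cons.bipartitions() <= t.bipartitions()

    def test_associative_and_commutative(self):
        a, b, c = (simulate_yule_tree(6, seed=s) for s in (5, 6, 7))
        assert strict_consensus([a, b, c]) == strict_consensus([c, a, b])
        assert strict_consensus([strict_consensus([a, b]), c]) == strict_consensus(
            [a, b, c]
        )

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError, match="leaf set"):
            strict_consensus([simulate_yule_tree(5), simulate_yule_tree(6)])

    def test_study_consensus_collapses_only_the_basal_node(self, study_fit):
        cons = strict_consensus(study_fit.mpts)
        splits = {frozenset(s) for s in cons.bipartitions()}
        pair = frozenset({"Bicorniphontodes_lacuna", "Bicorniphontodes_comptus"})
        trio = pair | {"Bicorniphontodes_huysi"}
        four = trio | {"Bicorniphontodes_horstgeorgei"}
        assert splits == {pair, trio, four}


class TestNewick:
    def test_simple_parse(self):
        t, support = tree_from_newick("(A,B,(C,D));")
        assert t.bipartitions() == frozenset({frozenset({"C", "D"})})
        assert support == {}

    def test_malformed_input_raises(self):
        with pytest.raises(ValueError, match="parse"):
            tree_from_newick("((A,B,(C;")

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_preserves_topology(self, seed):
        t = simulate_yule_tree(3 + seed % 6, seed=seed)
        again, _ = tree_from_newick(tree_to_newick(t))
        assert again == t

    def test_support_annotation_round_trip(self):
        t = quartet("a", "b", "c", "d")
        sup = {frozenset({"c", "d"}): 87.0}
        text = tree_to_newick(t, outgroup="a", support=sup)
        again, parsed = tree_from_newick(text)
        assert again == t
        assert parsed[frozenset({"c", "d"})] == 87.0

    def test_study_mpts_round_trip(self, study_fit):
        for t in study_fit.mpts:
            again, _ = tree_from_newick(
                tree_to_newick(t, outgroup="Laophontodes_typicus")
            )
            assert again == t


class TestSplitConstruction:
    def test_tree_from_bipartitions_inverts_bipartitions(self):
        for seed in range(5):
            t = simulate_yule_tree(7, seed=seed)
            rebuilt = tree_from_bipartitions(t.leaves, t.bipartitions())
            assert rebuilt == t

    def test_incompatible_splits_rejected(self):
        leaves = frozenset("abcde")
        with pytest.raises(ValueError, match="incompatible"):
            tree_from_bipartitions(
                leaves, [frozenset({"b", "c"}), frozenset({"c", "d"})]
            )
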