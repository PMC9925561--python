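import itertools

import dendropy
import numpy as np
import pytest

from mitoplasmid.phylo import (Alignment, collapse_low_support,
                               concat_alignments, filter_columns,
                               midpoint_root, neighbor_joining, node_support,
                               protein_distance, read_newick_string)


def leaf_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    return {(a.label, b.label): pdm.distance(a, b)
            for a, b in itertools.combinations(taxa, 2)}


def random_binary_tree(rng, n):
    """A random binary tree with uniform-random branch lengths in [0.1, 1]."""
    taxa = [f"t{i}" for i in range(n)]
    frags = {t: t for t in taxa}
    active = taxa[:]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        active = [x for x in active if x not in (a, b)]
        new = f"({frags[a]}:{rng.uniform(0.1, 1):.4f},{frags[b]}:{rng.uniform(0.1, 1):.4f})"
        key = a + b
        frags[key] = new
        active.append(key)
    a, b = active
    newick = (f"({frags[a]}:{rng.uniform(0.1, 1):.4f},"
              f"{frags[b]}:{rng.uniform(0.1, 1):.4f});")
    return read_newick_string(newick)


class TestAlignmentOps:
    def test_concat_two_columns(self):
        a = Alignment(["x", "y"], ["A", "C"])
        b = Alignment(["y", "x"], ["G", "T"])
        c = concat_alignments(a, b)
        assert c.rows == ["AT", "CG"]
        assert c.partitions == [("first", 0, 1), ("second", 1, 2)]

    def test_concat_id_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="only in first.*'y'"):
            concat_alignments(Alignment(["x", "y"], ["A", "C"]),
                              Alignment(["x", "z"], ["G", "T"]))

    def test_concat_positions_preserved(self):
        rng = np.random.default_rng(0)
        ids = ["a", "b", "c"]
        rows1 = ["".join(rng.choice(list("ACDEF"), 20)) for _ in ids]
        rows2 = ["".join(rng.choice(list("ACDEF"), 15)) for _ in ids]
        c = concat_alignments(Alignment(ids, rows1), Alignment(ids, rows2))
        for i in range(3):
            assert c.rows[i][:20] == rows1[i] and c.rows[i][20:] == rows2[i]

    def test_filter_gapless_unchanged(self):
        a = Alignment(["x", "y"], ["ACD", "ACE"])
        assert filter_columns(a, 0.0).rows == a.rows

    def test_filter_threshold_zero_drops_gapped_column(self):
        a = Alignment(["x", "y"], ["A-D", "ACE"])
        assert filter_columns(a, 0.0).rows == ["AD", "AE"]

    def test_filter_matches_per_column_oracle(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(5)]
        rows = ["".join(rng.choice(list("AC-"), 40)) for _ in ids]
        thr = 0.4
        got = filter_columns(Alignment(ids, rows), thr)
        keep = [j for j in range(40)
                if sum(r[j] == "-" for r in rows) / 5 <= thr]
        assert got.rows == ["".join(r[j] for j in keep) for r in rows]


class TestProteinDistance:
    def test_identical_rows_zero(self):
        D = protein_distance(Alignment(["x", "y"], ["ACDE", "ACDE"]))
        assert D[0, 1] == 0.0

    def test_half_different_p_is_half(self):
        D = protein_distance(Alignment(["x", "y"], ["AAAA", "AACC"]),
                             poisson=False)
        assert D[0, 1] == pytest.approx(0.5)
        Dp = protein_distance(Alignment(["x", "y"], ["AAAA", "AACC"]))
        assert Dp[0, 1] == pytest.approx(-np.log(0.5))

    def test_gap_columns_excluded(self):
        D = protein_distance(Alignment(["x", "y"], ["A-CD", "AEC-"]),
                             poisson=False)
        assert D[0, 1] == 0.0  # only columns 0 and 2 are shared, both equal

    def test_disjoint_gap_patterns_error(self):
        with pytest.raises(ValueError, match="no"):
            protein_distance(Alignment(["x", "y"], ["A-", "-C"]))


class TestNeighborJoining:
    def test_four_taxon_additive_metric_recovered_exactly(self):
        # ((A:1,B:2):1,(C:3,D:4):1) as an unrooted additive metric
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 0, 0]], dtype=float)
        D[2, 3] = D[3, 2] = 7.0
        tree = neighbor_joining(D, labels)
        got = leaf_distances(tree)
        for (a, b), d in got.items():
            i, j = labels.index(a), labels.index(b)
            assert d == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        got = leaf_distances(tree)
        assert got[("a", "b")] == pytest.approx(2)
        assert got[("a", "c")] == pytest.approx(3)
        assert got[("b", "c")] == pytest.approx(5)

    def test_recovers_random_binary_topologies(self):
        """NJ is exact on additive matrices from random trees <= 10 leaves."""
        rng = np.random.default_rng(13)
        for trial in range(30):
            n = int(rng.integers(4, 11))
            true = random_binary_tree(rng, n)
            labels = sorted(t.label for t in true.taxon_namespace)
            pdm = true.phylogenetic_distance_matrix()
            by_label = {t.label: t for t in true.taxon_namespace}
            D = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        D[i, j] = D[j, i] = pdm.distance(by_label[a], by_label[b])
            est = neighbor_joining(D, labels)
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=true.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=est.as_string(schema="newick"),
                                   schema="newick", taxon_namespace=tns)
            t1.is_rooted = t2.is_rooted = False
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(D, list("abc"))


class TestMidpointRoot:
    def test_two_leaf_tree_rooted_halfway(self):
        tree = midpoint_root(read_newick_string("(A:0.25,B:0.75);"))
        depths = {l.taxon.label: l.distance_from_root()
                  for l in tree.leaf_node_iter()}
        assert depths["A"] == pytest.approx(0.5, abs=1e-9)
        assert depths["B"] == pytest.approx(0.5, abs=1e-9)

    def test_diameter_endpoints_equidistant(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree(rng, n)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = list(tree.taxon_namespace)
            diameter = max(pdm.distance(a, b)
                           for a, b in itertools.combinations(taxa, 2))
            rooted = midpoint_root(tree)
            depths = [l.distance_from_root() for l in rooted.leaf_node_iter()]
            assert max(depths) == pytest.approx(diameter / 2, abs=1e-9)

    def test_minimizes_max_root_to_leaf_depth(self):
        """diameter/2 is the optimum over every possible root placement."""
        rng = np.random.default_rng(15)
        for _ in range(5):
            tree = random_binary_tree(rng, int(rng.integers(4, 9)))
            pdm = tree.phylogenetic_distance_matrix()
            taxa = list(tree.taxon_namespace)
            diameter = max(pdm.distance(a, b)
                           for a, b in itertools.combinations(taxa, 2))
            rooted = midpoint_root(tree)
            achieved = max(l.distance_from_root()
                           for l in rooted.leaf_node_iter())
            # any root r has max_l d(r,l) >= diameter/2 by the triangle
            # inequality, so equality certifies the minimum
            assert achieved == pytest.approx(diameter / 2, abs=1e-9)


class TestCollapse:
    def test_all_supported_unchanged(self):
        t = read_newick_string("((A:1,B:1)100:1,(C:1,D:1)99:1);")
        out = collapse_low_support(t, 95)
        assert len(out.internal_nodes()) == len(t.internal_nodes())

    def test_all_zero_becomes_star(self):
        t = read_newick_string("((A:1,B:1)0:1,((C:1,D:1)0:1,E:1)0:1);")
        out = collapse_low_support(t, 95)
        assert len(out.seed_node.child_nodes()) == 5

    def test_threshold_is_strict_below_95(self):
        t = read_newick_string("((A:1,B:1)95:1,(C:1,D:1)94:1);")
        out = collapse_low_support(t, 95)
        kept = [node_support(n) for n in out.preorder_internal_node_iter()
                if n.parent_node is not None]
        assert kept == [95.0]

    def test_collapse_is_idempotent(self):
        t = read_newick_string("(((A:1,B:1)40:1,(C:1,D:1)97:1)96:1,(E:1,F:1)20:1);")
        once = collapse_low_support(t, 95)
        twice = collapse_low_support(once, 95)
        assert once.as_string(schema="newick") == twice.as_string(schema="newick")

    def test_contracted_edges_match_per_edge_oracle(self):
        newick = "(((A:1,B:1)40:1,(C:1,D:1)97:1)96:1,((E:1,F:1)20:1,G:1)99:1);"
        t = read_newick_string(newick)
        below = sum(1 for n in t.preorder_internal_node_iter()
                    if n.parent_node is not None and node_support(n) < 95)
        before = sum(1 for n in t.preorder_internal_node_iter()
                     if n.parent_node is not None)
        out = collapse_low_support(t, 95)
        after = sum(1 for n in out.preorder_internal_node_iter()
                    if n.parent_node is not None)
        assert before - after == below

    def test_leaf_set_and_root_depths_preserved(self):
        # a collapsed edge's length is redistributed to its children, so
        # every root-to-leaf depth is unchanged (collapsing a positive
        # branch cannot preserve all leaf-to-leaf paths simultaneously)
        newick = "(((A:1,B:2)40:3,(C:1,D:1)97:2)96:1,E:4);"
        t = read_newick_string(newick)
        out = collapse_low_support(t, 95)
        assert {l.taxon.label for l in out.leaf_node_iter()} == set("ABCDE")
        before = {l.taxon.label: l.distance_from_root()
                  for l in t.leaf_node_iter()}
        after = {l.taxon.label: l.distance_from_root()
                 for l in out.leaf_node_iter()}
        for leaf, d in before.items():
            assert after[leaf] == pytest.approx(d, abs=1e-9)
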