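"""Neighbor joining, bootstrap, and tree-comparison tests."""
import dendropy
import numpy as np
import pytest

from its2repeats.align import Alignment
from its2repeats.distances import DistanceMatrix
from its2repeats.trees import (
    bipartitions,
    bootstrap_support,
    compare_trees,
    nj_tree,
    patristic_matrix,
    root_on_outgroup,
)

from conftest import random_seq


def random_additive_case(rng, n_taxa):
    """A random binary tree topology plus its exact leaf distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (j, i):
            child = nodes.pop(k)
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 0.4))
    # final trifurcation
        nodes.append(parent)
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(0.05, 0.4))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    dm = DistanceMatrix(labels=labels, values=patristic_matrix(tree, labels))
    return tree, dm


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            labels=["a", "b", "c"],
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(labels=["a", "b"], values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_additive_five_taxon_matrix_reproduced(self, rng):
        _, dm = random_additive_case(rng, 5)
        got = patristic_matrix(nj_tree(dm), dm.labels)
        assert np.allclose(got, dm.values, atol=1e-9)

    def test_topology_recovery_on_random_additive_matrices(self, rng):
        for _ in range(20):
            true_tree, dm = random_additive_case(rng, int(rng.integers(6, 11)))
            est = nj_tree(dm)
            assert bipartitions(est) == bipartitions(true_tree)

    def test_label_order_invariance(self, rng):
        _, dm = random_additive_case(rng, 7)
        perm = list(rng.permutation(len(dm.labels)))
        dm2 = dm.reordered([dm.labels[i] for i in perm])
        assert bipartitions(nj_tree(dm)) == bipartitions(nj_tree(dm2))

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        """Independent NJ implementation recovers the same unrooted topology."""
        import skbio

        _, dm = random_additive_case(rng, 8)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.labels))
        ours = nj_tree(dm)
        sk_bips = set()
        labels = set(dm.labels)
        ref = min(labels)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(labels - side)
            if 1 < len(side) < len(labels):
                sk_bips.add(side)
        assert bipartitions(ours) == sk_bips

    def test_branch_lengths_never_negative(self, rng):
        # noisy (non-additive) matrices still give non-negative branches
        for _ in range(10):
            _, dm = random_additive_case(rng, 6)
            noisy = dm.values + rng.uniform(0, 0.05, dm.values.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            tree = nj_tree(DistanceMatrix(labels=dm.labels, values=noisy))
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0.0


def clade_alignment(rng, n_per_clade=4, length=400, within=0.01, between=0.3):
    from its2repeats.simulate import mutate_jc

    root = random_seq(rng, length)
    a_anc = mutate_jc(root, between / 2, rng)
    b_anc = mutate_jc(root, between / 2, rng)
    labels, rows = [], []
    for i in range(n_per_clade):
        labels.append(f"a{i}")
        rows.append(mutate_jc(a_anc, within, rng))
        labels.append(f"b{i}")
        rows.append(mutate_jc(b_anc, within, rng))
    return Alignment(labels=labels, rows=rows)


class TestBootstrap:
    def test_separated_clades_strongly_supported(self, rng):
        aln = clade_alignment(rng)
        tree, supports = bootstrap_support(aln, n_replicates=100, seed=4)
        a_side = frozenset(l for l in aln.labels if l.startswith("a"))
        b_side = frozenset(l for l in aln.labels if l.startswith("b"))
        sup = supports.get(a_side, supports.get(b_side))
        assert sup is not None and sup >= 95.0

    def test_seeded_determinism(self, rng):
        aln = clade_alignment(rng, n_per_clade=3, length=200)
        _, s1 = bootstrap_support(aln, n_replicates=50, seed=9)
        _, s2 = bootstrap_support(aln, n_replicates=50, seed=9)
        assert s1 == s2

    def test_identical_sequences_star_degenerate(self, rng):
        seq = random_seq(rng, 100)
        aln = Alignment(labels=list("abcd"), rows=[seq] * 4)
        tree, supports = bootstrap_support(aln, n_replicates=20, seed=0)
        assert all(0.0 <= s <= 100.0 for s in supports.values())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length == pytest.approx(0.0)

    def test_too_few_columns_rejected(self):
        aln = Alignment(labels=["a", "b", "c"], rows=["A", "A", "C"])
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=10, seed=0)


class TestCompareTrees:
    def test_tree_versus_itself(self):
        nwk = "((a,b),(c,d),e);"
        cmp = compare_trees(nwk, nwk)
        assert cmp.distance == 0 and cmp.unique_to_a == []

    def test_single_nni_on_five_leaves(self):
        # oracle: ((a,b),(c,d),e) has splits {ab},{cd}; ((a,c),(b,d),e) has
        # {ac},{bd}; the symmetric difference is 4... restricted to shared
        # non-trivial splits each tree holds 2, none shared -> distance 4.
        t1 = "((a,b),(c,d),e);"
        t2 = "((a,c),(b,d),e);"
        cmp = compare_trees(t1, t2)
        assert cmp.distance == 4
        # a single-split rearrangement keeping {cd}: distance 2
        t3 = "((a,e),(c,d),b);"
        cmp2 = compare_trees(t1, t3)
        assert cmp2.distance == 2

    def test_caterpillar_versus_balanced_six_leaves(self):
        cat = "(a,(b,(c,(d,(e,f)))));"
        bal = "((a,(b,c)),(d,(e,f)));"
        cmp = compare_trees(cat, bal)
        # brute-force split enumeration oracle
        def splits(nwk):
            t = dendropy.Tree.get(data=nwk, schema="newick")
            return bipartitions(t)
        expected = len(splits(cat) ^ splits(bal))
        assert cmp.distance == expected

    def test_agrees_with_dendropy_rf(self, rng):
        t1, dm = random_additive_case(rng, 8)
        t2, _ = random_additive_case(rng, 8)
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        d1 = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions(); d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert compare_trees(t1, t2).distance == expected

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets differ"):
            compare_trees("((a,b),c);", "((a,b),d);")


class TestRooting:
    def test_root_on_single_outgroup(self, rng):
        _, dm = random_additive_case(rng, 6)
        tree = nj_tree(dm)
        rooted = root_on_outgroup(tree, ["t0"])
        assert rooted.is_rooted
        children = rooted.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert frozenset({"t0"}) in sides

    def test_absent_outgroup_rejected(self, rng):
        _, dm = random_additive_case(rng, 5)
        with pytest.raises(ValueError, match="absent"):
            root_on_outgroup(nj_tree(dm), ["nope"])
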