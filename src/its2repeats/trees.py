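"""Neighbor joining, bootstrap support, and bipartition bookkeeping.

Trees are carried as :class:`dendropy.Tree` objects (unrooted by default,
branch lengths in substitutions/site, bootstrap support as internal node
labels in percent).  The NJ agglomeration itself is implemented here with the
conventions used throughout the package: ties broken toward the lowest label
index, negative branch-length estimates clamped to zero with the deficit
moved to the sister branch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .align import Alignment
from .distances import DistanceMatrix, jc_matrix_from_codes

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "compare_trees",
    "root_on_outgroup",
    "patristic_matrix",
    "TreeComparison",
]


def _clamp_pair(la: float, lb: float, total: float) -> tuple[float, float]:
    """Clamp a negative branch estimate to 0, moving the deficit to the sister."""
    if la < 0:
        return 0.0, max(total, 0.0)
    if lb < 0:
        return max(total, 0.0), 0.0
    return la, lb


def nj_tree(dmatrix: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration of a labelled distance matrix.

    Deterministic: the minimal Q entry is taken in row-major order, so ties
    resolve toward the lowest label indices.  Returns an unrooted tree whose
    seed node is the final trifurcation (or a bifurcation for 3 taxa joined
    last).  Requires at least three labels.
    """
    n = len(dmatrix)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    tns = dendropy.TaxonNamespace(list(dmatrix.labels))
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(label)) for label in dmatrix.labels
    ]
    D = dmatrix.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, dij)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    root = dendropy.Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, ln in zip(nodes, lengths):
        root.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels.

    Each bipartition is normalised to the side *not* containing the
    lexicographically smallest leaf label, so sets are comparable across
    trees over the same leaves regardless of rooting.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves):
            out.add(side)
    return out


def _clade_sides(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = side if ref not in side else leaves - side
        if 1 < len(key) < len(leaves):
            out[key] = node
    return out


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    tree: dendropy.Tree | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap support for an NJ tree of the alignment.

    Columns are resampled with replacement, an NJ tree is built per replicate
    from JC distances (pairwise deletion; saturated replicate pairs are capped
    rather than aborted), and support is the percentage of replicates whose
    tree contains each bipartition of the original tree.  Supports are written
    onto the original tree's internal node labels (integer percent) and also
    returned keyed by normalised bipartition.  Seeded and deterministic.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if alignment.length < 2:
        raise ValueError("alignment must have >= 2 columns")
    codes = alignment.codes()
    labels = list(alignment.labels)
    if tree is None:
        tree = nj_tree(jc_matrix_from_codes(labels, codes))
    sides = _clade_sides(tree)
    counts = {side: 0 for side in sides}
    rng = np.random.default_rng(seed)
    length = codes.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        dm = jc_matrix_from_codes(labels, codes[:, idx], saturation="cap")
        rep = nj_tree(dm)
        rep_bips = bipartitions(rep)
        for side in counts:
            if side in rep_bips:
                counts[side] += 1
    supports = {side: 100.0 * c / n_replicates for side, c in counts.items()}
    for side, node in sides.items():
        node.label = str(int(round(supports[side])))
    return tree, supports


@dataclass
class TreeComparison:
    """Robinson-Foulds style bipartition comparison of two trees."""

    shared: int
    distance: int
    unique_to_a: list[tuple[str, ...]] = field(default_factory=list)
    unique_to_b: list[tuple[str, ...]] = field(default_factory=list)


def _as_tree(tree, taxon_namespace=None) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree, schema="newick", taxon_namespace=taxon_namespace
    )


def compare_trees(tree_a, tree_b) -> TreeComparison:
    """Symmetric-difference count of non-trivial bipartitions plus conflicts.

    Accepts dendropy trees or newick strings; both trees must cover the same
    leaf set.
    """
    ta = _as_tree(tree_a)
    tb = _as_tree(tree_b)
    leaves_a = {l.taxon.label for l in ta.leaf_node_iter()}
    leaves_b = {l.taxon.label for l in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError(
            f"leaf sets differ: only in first={sorted(leaves_a - leaves_b)}, "
            f"only in second={sorted(leaves_b - leaves_a)}"
        )
    ba = bipartitions(ta)
    bb = bipartitions(tb)
    return TreeComparison(
        shared=len(ba & bb),
        distance=len(ba ^ bb),
        unique_to_a=sorted(tuple(sorted(s)) for s in ba - bb),
        unique_to_b=sorted(tuple(sorted(s)) for s in bb - ba),
    )


def root_on_outgroup(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Root a copy of the tree on the branch subtending the outgroup taxa."""
    if not outgroup:
        raise ValueError("no outgroup given")
    t = _as_tree(tree.as_string(schema="newick"))
    labels = {l.taxon.label for l in t.leaf_node_iter()}
    missing = [o for o in outgroup if o not in labels]
    if missing:
        raise ValueError(f"outgroup taxa absent from the tree: {missing}")
    if set(outgroup) == labels:
        raise ValueError("outgroup cannot contain every leaf")
    taxa = [t.taxon_namespace.get_taxon(o) for o in outgroup]
    t.is_rooted = True  # treat the seed node as root while locating the MRCA
    mrca = t.mrca(taxa=taxa)
    if mrca is t.seed_node:
        # reseed on an ingroup leaf so the outgroup forms a proper clade
        ingroup_leaf = next(
            l for l in t.leaf_node_iter() if l.taxon.label not in set(outgroup)
        )
        t.reroot_at_edge(ingroup_leaf.edge, update_bipartitions=False)
        mrca = t.mrca(taxa=taxa)
    edge = mrca.edge
    half = (edge.length or 0.0) / 2.0
    t.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    t.is_rooted = True
    return t


def patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return out
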