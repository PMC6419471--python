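"""Neighbor-joining trees on K2P matrices, midpoint rooting, newick I/O.

The Saitou–Nei agglomeration is implemented directly so that tie-breaks
are deterministic (lowest index pair wins); trees are held as
:class:`dendropy.Tree` objects, which also provide newick round-trips
and midpoint rerooting.  Negative branch-length estimates — a normal
NJ artifact — are clamped to zero and the clamped total is logged.
"""

from __future__ import annotations

import logging
import math

import dendropy
import numpy as np

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; requires a complete matrix.

    Terminates at three remaining nodes with a trifurcating root (the
    tree is unrooted until :func:`midpoint_root`), or at two with a
    root splitting the final edge evenly.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    iu = np.triu_indices(n, k=1)
    if np.isnan(dm.d[iu]).any():
        raise ValueError(
            "distance matrix has missing cells; impute or drop those records before NJ"
        )

    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for tid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(tid))
        nodes.append(node)
    D = dm.d.copy()
    active = list(range(n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest flat index = lexicographically lowest (i, j) pair
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_d
        D[:, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    root = dendropy.Node()
    if len(active) == 2:
        i, j = active
        half = D[i, j] / 2.0
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        nodes[i].edge.length = clamp(half)
        nodes[j].edge.length = clamp(half)
    else:
        i, j, k = active
        # three-point formulas for the star lengths
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, length in ((i, li), (j, lj), (k, lk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(length)
    tree.seed_node = root
    tree.is_rooted = False
    if clamped > 0:
        logger.info("clamped %.6g of negative NJ branch length to zero", clamped)
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    A zero-diameter tree (all branch lengths zero) cannot define a
    midpoint; the tree is then rooted at the first internal node with a
    warning.
    """
    t = tree.clone(depth=1)
    leaves = [lf for lf in t.leaf_node_iter()]
    if len(leaves) == 2:
        total = sum(lf.edge.length or 0.0 for lf in leaves)
        for lf in leaves:
            lf.edge.length = total / 2.0
        t.is_rooted = True
        return t
    pdm = t.phylogenetic_distance_matrix()
    diameter = max(
        (pdm.patristic_distance(a, b) for a, b in pdm.distinct_taxon_pair_iter()),
        default=0.0,
    )
    if diameter <= 0.0:
        logger.warning("zero-diameter tree: rooting at first internal node")
        t.is_rooted = True
        return t
    t.reroot_at_midpoint(update_bipartitions=True)
    t.is_rooted = True
    return t


def leaf_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Patristic distances between all leaf pairs, keyed by sorted labels."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    for a, b in pdm.distinct_taxon_pair_iter():
        key = tuple(sorted((a.label, b.label)))
        out[key] = pdm.patristic_distance(a, b)
    return out


def clade_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Leaf-label set of every internal edge (topology fingerprint).

    Trivial splits (single leaves, full leaf set) are omitted, and on an
    unrooted tree each bipartition is represented by whichever side is
    lexicographically smaller, so topologically identical trees compare
    equal regardless of rooting.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - clade
        if len(clade) <= 1 or len(other) <= 1:
            continue
        out.add(min(clade, other, key=lambda s: sorted(s)))
    return out


def is_monophyletic(tree: dendropy.Tree, leaf_labels: set[str]) -> bool:
    """True iff the labels form a complete clade of the rooted tree."""
    taxa = [t for t in tree.taxon_namespace if t.label in leaf_labels]
    if len(taxa) != len(leaf_labels):
        raise ValueError("labels not all present in tree")
    if len(taxa) == 1:
        return True
    mrca = tree.mrca(taxa=taxa)
    under = {lf.taxon.label for lf in mrca.leaf_iter()}
    return under == set(leaf_labels)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def path_matrix_close(a: dendropy.Tree, b: dendropy.Tree, tol: float = 1e-9) -> bool:
    """True iff two trees induce the same leaf-to-leaf path lengths."""
    pa, pb = leaf_path_lengths(a), leaf_path_lengths(b)
    if pa.keys() != pb.keys():
        return False
    return all(math.isclose(pa[k], pb[k], abs_tol=tol) for k in pa)
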