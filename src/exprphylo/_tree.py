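"""Internal tree plumbing shared by the inference modules.

Two representations are used: dendropy.Tree at the public surface (Newick
IO, rooting, visualization) and a slim mutable node structure (`SNode`) for
topology search, where dendropy's bookkeeping would dominate the runtime.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

__all__ = [
    "SNode",
    "leaf_labels",
    "splits",
    "split_lengths",
    "all_unrooted_topologies",
    "count_unrooted_topologies",
    "nni_neighbors",
    "snode_to_dendropy",
    "dendropy_to_snode",
    "clone",
]


class SNode:
    """Rooted binary search-tree node; ``taxon`` is an integer index at leaves."""

    __slots__ = ("children", "parent", "taxon", "length")

    def __init__(self, taxon: int | None = None, length: float = 0.0):
        self.children: list["SNode"] = []
        self.parent: "SNode" | None = None
        self.taxon = taxon
        self.length = length

    def add(self, child: "SNode") -> "SNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def newick(self, names=None) -> str:
        def rec(n):
            if n.is_leaf:
                return str(n.taxon) if names is None else names[n.taxon]
            return "(" + ",".join(rec(c) for c in n.children) + ")"

        return rec(self) + ";"


def clone(node: SNode) -> SNode:
    new = SNode(taxon=node.taxon, length=node.length)
    for c in node.children:
        new.add(clone(c))
    return new


# ---------------------------------------------------------------------------
# Topology enumeration and NNI (unrooted binary trees, rooted-at-taxon-0 form)
# ---------------------------------------------------------------------------
# An unrooted binary topology on taxa {0..n-1} is stored as a rooted tree
# whose root has two children: leaf 0 and the binary subtree of the rest.
# The root's two edges jointly stand for leaf 0's pendant edge.

def _base_tree() -> SNode:
    root = SNode()
    root.add(SNode(taxon=0))
    inner = root.add(SNode())
    inner.add(SNode(taxon=1))
    inner.add(SNode(taxon=2))
    return root


def _insertion_points(root: SNode) -> list[SNode]:
    # every node below the root except leaf 0; "insert above node c"
    pts = []
    for n in root.postorder():
        if n is root:
            continue
        if n.parent is root and n.is_leaf and n.taxon == 0:
            continue
        pts.append(n)
    return pts


def _insert_above(c: SNode, leaf: SNode) -> SNode:
    """Split the edge above ``c`` with a new internal node carrying ``leaf``."""
    p = c.parent
    mid = SNode()
    p.children[p.children.index(c)] = mid
    mid.parent = p
    mid.add(c)
    mid.add(leaf)
    return mid


def _remove_insertion(mid: SNode, c: SNode) -> None:
    p = mid.parent
    p.children[p.children.index(mid)] = c
    c.parent = p


def all_unrooted_topologies(n_taxa: int):
    """Yield every unrooted binary topology on ``n_taxa`` taxa (SNode form).

    (2n-5)!! topologies; the yielded tree is reused between iterations —
    clone it if it must outlive the loop.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa for an unrooted topology")
    root = _base_tree()

    def rec(k):
        if k == n_taxa:
            yield root
            return
        for c in list(_insertion_points(root)):
            leaf = SNode(taxon=k)
            mid = _insert_above(c, leaf)
            yield from rec(k + 1)
            _remove_insertion(mid, c)

    yield from rec(3)


def count_unrooted_topologies(n_taxa: int) -> int:
    out = 1
    for k in range(4, n_taxa + 1):
        out *= 2 * k - 5
    return out


def nni_neighbors(root: SNode):
    """Yield (fresh) SNode trees one nearest-neighbor interchange away.

    Internal edges of the unrooted topology are the edges (p, c) with c
    internal and p below the root; each yields two interchanges.
    """
    nodes = [n for n in root.postorder() if n.children and n.parent is not None and n.parent is not root]
    # also internal nodes hanging directly off the root's non-leaf child? No:
    # edge (root, inner) is leaf 0's pendant edge; every other internal edge
    # has p != root, covered above.
    for c in nodes:
        p = c.parent
        s = p.children[0] if p.children[1] is c else p.children[1]
        for a in list(c.children):
            # swap subtrees s <-> a
            pi, ci = p.children.index(s), c.children.index(a)
            p.children[pi], c.children[ci] = a, s
            a.parent, s.parent = p, c
            yield clone(root)
            p.children[pi], c.children[ci] = s, a
            a.parent, s.parent = c, p


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def snode_to_dendropy(
    root: SNode,
    names: list[str],
    taxon_namespace: dendropy.TaxonNamespace | None = None,
    unroot: bool = True,
    default_length: float | None = None,
) -> dendropy.Tree:
    """Convert a rooted-at-taxon-0 search tree to a dendropy tree.

    With ``unroot`` the degree-2 root is suppressed, yielding the standard
    trifurcating-root representation of an unrooted tree.
    """
    tns = taxon_namespace or dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)

    def rec(snode, dnode):
        for c in snode.children:
            child = dendropy.Node()
            child.edge.length = default_length if default_length is not None else c.length
            if c.is_leaf:
                child.taxon = tns.get_taxon(names[c.taxon])
            dnode.add_child(child)
            rec(c, child)

    rec(root, tree.seed_node)
    if unroot:
        tree.is_rooted = False
        tree.collapse_basal_bifurcation()
    else:
        tree.is_rooted = True
    return tree


def dendropy_to_snode(tree: dendropy.Tree, index_of: dict[str, int]) -> SNode:
    """Convert a dendropy tree to an SNode tree (any degree; root preserved)."""

    def rec(dnode):
        s = SNode(
            taxon=None if dnode.taxon is None else index_of[dnode.taxon.label],
            length=dnode.edge.length or 0.0,
        )
        for c in dnode.child_nodes():
            s.add(rec(c))
        return s

    return rec(tree.seed_node)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_leafsets(tree: dendropy.Tree) -> dict:
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for c in node.child_nodes():
                s |= below[c]
            below[node] = s
    return below


def splits(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as frozensets of the side NOT containing the
    lexicographically smallest leaf (a canonical, rooting-free encoding)."""
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    out = set()
    below = _node_leafsets(tree)
    for node, s in below.items():
        side = all_leaves - s if ref in s else s
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def split_lengths(tree: dendropy.Tree) -> dict:
    """Map each non-trivial split to its edge length (summing the two root
    edges of a bifurcating root, which form one unrooted edge)."""
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    below = _node_leafsets(tree)
    out: dict = {}
    root = tree.seed_node
    rc = root.child_nodes()
    skip = rc[1] if len(rc) == 2 else None  # avoid double-counting root edge
    for node, s in below.items():
        if node is root or node is skip:
            continue
        side = all_leaves - s if ref in s else s
        if not (1 < len(side) < len(all_leaves) - 1):
            continue
        length = node.edge.length or 0.0
        if node.parent_node is root and skip is not None:
            length += skip.edge.length or 0.0
        out[side] = length
    return out


def path_length_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    taxa = {t.label: t for t in tns}
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        out[i, j] = out[j, i] = d
    return out
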